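Transcript_name	Treated1	Treated2	Treated3	Untreated1	Untreated2	Untreated3	Untreated4
FBgn0000003	0	0	1	0	0	0	0
FBgn0000008	140	88	70	92	161	76	70
FBgn0000014	4	0	0	5	1	0	0
FBgn0000015	1	0	0	0	2	1	2
FBgn0000017	6205	3072	3334	4664	8714	3564	3150
FBgn0000018	722	299	308	583	761	245	310
FBgn0000022	0	0	0	0	1	0	0
FBgn0000024	10	7	5	10	11	3	3
FBgn0000028	0	1	1	0	1	0	0
FBgn0000032	1698	696	757	1446	1713	615	672
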