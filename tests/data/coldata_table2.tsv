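sample_name	condition
treated1	treated
treated2	treated
treated3	treated
untreated1	untreated
untreated2	untreated
untreated3	untreated
untreated4	untreated
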