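# Methods

This note documents the statistical models behind `degconsensus`, the
parameters that matter, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## Problem setting

Input is a genes × samples table of non-negative integer read counts with
exactly two condition groups (reference and treatment, n₁ and n₂
replicates). The goal is a per-gene call: differentially expressed (DEG) or
not, with direction. Because DE methods built on different statistical
principles disagree on the margins, the pipeline runs up to four engines
and intersects their thresholded DEG sets. Intersection can only remove
false positives relative to any member (the consensus is a subset of every
member's set), so consensus specificity ≥ every member's specificity and
consensus sensitivity ≤ every member's sensitivity — an exact set-theoretic
theorem that the test suite verifies empirically against simulated gold
standards.

## Shared plumbing

**Expression filter.** All engines test the same universe: genes with
CPM > 1 in at least min(n₁, n₂) samples (plain library-size CPM). Genes
with all-zero counts would otherwise break every engine's normalization.

**Fold change.** log2FC = log2((m₂ + 0.5)/(m₁ + 0.5)) where m₁, m₂ are
normalized condition means on the count scale. The 0.5 pseudocount keeps
the value finite, so the status rule (`up` if > 0, `down` if < 0,
`zero_value` if exactly 0) is total.

**Score unification.** Each engine exposes a single thresholdable `fdr`
column: Benjamini–Hochberg-adjusted p-values for the two frequentist
engines, and 1 − probability-of-DE for the nonparametric and
empirical-Bayes engines. These are not the same quantity — an adjusted
p-value bounds the FDR frequentistly, a posterior probability is a Bayesian
statement — but a single cut applied to all four is what makes a uniform
consensus threshold possible; the run log records this semantic
prominently.

**Normalization.** TMM (trimmed mean of M-values): reference sample =
closest upper-quartile CPM to the mean upper-quartile; genes positive in
both samples are trimmed 30% per tail on M and 5% per tail on A; factor =
2^(precision-weighted mean M) with delta-method weights; factors rescaled
to geometric mean 1. Median-of-ratios: per-sample median of count /
per-gene geometric mean over genes positive everywhere. Trim fractions are
fixed, not configurable.

## Engines

**Exact conditional NB test (`nb_exact`).** Counts are scaled to a common
effective library size (TMM × library size, geometric mean as the common
size) and summed per group; rounding to integers happens at the group-sum
level. A group sum of n iid NB(μ, φ) draws is NB with mean nμ and size
n/φ. Conditioning on the total s, the two-sided p-value enumerates every
split (a, s − a) and sums the normalized probabilities of splits no more
likely than the observed one — ties included, no doubling. At φ = 0 this
reduces exactly to binomial(s, n₁/(n₁+n₂)) tail sums, which the tests
exploit as an integer-arithmetic oracle. Totals above 10 000 are evaluated
on a ±40-SD window of the conditional; the omitted mass is below 1e-300
relative and the window always contains the observed split.

**NB Wald test (`nb_wald`).** Size-factor-normalized condition means,
delta-method variance Var(x/s) ≈ μ/s + φμ² propagated through the log2,
z = log2FC/SE, p = 2Φ(−|z|). Using the normal rather than a t reference is
the family convention; at 5 + 5 replicates it is mildly anti-conservative
(null rejection ≈ 6% at α = 5% in the calibration suite), which is within
the accepted band and typical of plug-in Wald tests.

**Dispersion.** Raw per-gene moment estimate φ̂ = max(0, (s² − μ)/μ²) with
the variance pooled *within* conditions (so true DE does not inflate it);
common value = median of positive estimates. Shrinkage φ̃ = 0.7·target +
0.3·φ̂ — target = common value for the exact engine, and for the Wald
engine a mean-dispersion trend a/μ + b fitted by least squares on
log φ (a, b ≥ 0, falling back to the common value if fewer than ten genes
inform the fit). Everything is closed-form or a deterministic small
optimization; there is no sampling anywhere in the engines.

**Noise engine (`noise`).** Signal per gene: M = log2 ratio and
D = absolute difference of the condition means of CPM (prior 0.5, plain
library-size CPM — the factor-free default of this family). Noise: the
same (M, D) computed between every within-condition replicate pair,
pooled over all genes and pairs. Probability of DE = fraction of noise
points with |M₀| < |M| *and* D₀ < D, both strict, so a gene with zero
signal gets probability 0. At least one condition must have ≥ 2 replicates;
with none, the engine refuses (no simulated technical replicates).
The dominance count is computed in fixed-size chunks to bound memory.

**Empirical-Bayes engine (`eb`).** Two-hypothesis beta-NB mixture:
x_gi ~ NB(size r_g·s_i, success q) with q ~ Beta(α, β) shared by all
samples (EE) or drawn independently per condition (DE). Integrating q gives
marginals in closed form through Beta functions; per-sample combinatorial
terms cancel between hypotheses but are included for completeness. r_g by
moments (m²/(v − m), within-condition pooled v; Poisson-like genes capped
at r = 10⁶), (α, β) by moments of the pooled q̂ = r/(r + m) distribution.
The DE weight π is fitted by EM on the two marginal likelihoods:
deterministic start π = 0.5, tolerance 1e-6 on π, at most 100 iterations,
warning (not an error) on non-convergence. PPDE = πL_DE/(πL_DE + (1−π)L_EE).

## Consensus, Venn, evaluation

Thresholds are applied per method *before* intersection: |log2FC| ≥ cut
(inclusive, default 2) and score < cut (strict, default 0.01). The
boundary conventions differ deliberately — the fold-change rule is stated
as an inclusive bound, the score rule as a strict one — and the tests pin
both. The consensus table carries the common status or `Inconsistent`,
the mean and sample SD (ddof = 1; NA for one method) of the member log2FCs,
then member log2FCs, then member scores last. Genes filtered out of one
member's universe count as not-DEG for that member and therefore cannot be
consensus genes. Venn region counts are exact per-gene membership tallies
for up to four sets; a diagram is drawn for two or three sets (the
four-set region counts are available as a table).

Evaluation universe = tested genes ∩ gold-standard genes (configurable to
the full tested universe). The positive class is "called a DEG"; direction
disagreement does not demote a true positive but is reported separately as
direction accuracy. Metrics with a zero denominator are NA, never 0.

## Simulator

The generator emulates a bulk two-condition RNA-seq experiment: per-gene
baseline means log-normal (defaults: log-mean 4.0, log-SD 1.5, i.e. a
median of ~55 counts spanning single digits to tens of thousands), an
exactly realized DE fraction (round(G·π_DE), signs balanced up/down) with
the fold change split symmetrically 2^(±lfc/2) so group library sizes stay
comparable, uniform per-sample library factors (default 0.7–1.3), and NB
counts with constant dispersion (default φ = 0.1, Poisson at φ = 0). The
default design — 2000 genes, 5 + 5 replicates, 10% DEGs at |log2FC| = 2 —
is a moderately easy, realistic bulk benchmark. Draws come from a single
seeded NumPy PCG64 stream in documented order, so identical seeds give
byte-identical output files.

What the simulator does *not* emulate: mean-dependent dispersion trends,
gene-length and GC effects, correlated genes, outlier samples, and
asymmetric fold-change distributions. Passing the recovery and calibration
suites therefore shows the engines are correct under their own model
assumptions, not that they rank well on any particular real dataset.

## Problem sizes and numerical choices

The calibration suite uses a 5000-gene all-null design and the recovery
suite the 2000-gene reference design; the set-theory and oracle suites run
on toys of 100–300 genes. These sizes give stable rates (Monte-Carlo SE on
the null rejection fraction ≈ 0.3 percentage points) while keeping the
whole suite in seconds. Other fixed choices: BH via the standard step-up
(statsmodels), exact-test tie tolerance 1e-12 relative, EM and trend-fit
fallbacks as above, and case-insensitive sample-name matching with a
warning (the two input tables frequently disagree in capitalization;
condition *levels* remain case-sensitive).

## Limitations

Two-group designs only: no covariates, pairing, or >2 conditions. The
engines are native implementations of each statistical family, simplified
relative to the mature packages of those families (no quantile-adjusted
conditional likelihood, no Cox–Reid adjusted profile likelihood, no GLM
machinery, single-pass hyperparameter estimation); they satisfy the
pipeline contract — per-gene {log2FC, score, status} with calibrated null
behaviour — but are not drop-in numerical replacements for those packages.
The consensus is intersection-only by design; union, majority-vote and
p-value-combination modes are out of scope.
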