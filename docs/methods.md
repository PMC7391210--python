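# Methods

This note documents the statistical procedures implemented in `exomir`, the
assumptions behind them, the defaults of the synthetic-data generator, and the
numerical choices made where the underlying methods literature leaves room.

## Study design being modelled

The pipeline mirrors a two-cohort circulating-biomarker design: a small
RNA-seq **discovery set** (here 6 cases vs 6 controls) screened for
differentially expressed miRNAs and mined for stably expressed endogenous
references, and a larger qRT-PCR **validation set** (50 vs 25) in which
shortlisted markers are quantified relative to the chosen references and
evaluated diagnostically. All sample sizes, thresholds and effect scales used
as defaults come from that design.

## Differential expression

Counts are modelled as gamma-Poisson (negative binomial) with variance
μ + αμ². Library-size factors use the median-of-ratios estimator: the factor
of sample *j* is the median over genes (restricted to genes with positive
counts in every sample) of count_ij divided by the gene's geometric mean.
TPM applies no length correction — mature miRNAs are all ~22 nt, and the
count-to-TPM convention for miRNA-seq scales counts directly.

The test conditions on each gene's total count K across both groups and asks
whether the observed case share is extreme under independence. The case and
control totals are treated as NB with mean q·Σs_j and variance
q·Σs_j + αq²·Σs_j² (q the mean normalized count); the conditional law of the
case total given K is formed by normalizing the product of the two pmfs over
all splits, and the two-sided P doubles the smaller tail (capped at 1). With
α = 0 this reduces exactly to the conditional binomial test, which the test
suite verifies against explicit enumeration.

Per-gene dispersion is method-of-moments on normalized counts using the
pooled within-group variance minus the expected shot noise, floored at zero,
then blended with a least-squares mean-trend fit α(q) = a₀ + a₁/q by taking
the per-gene maximum. This is deliberately simpler than historical
local-regression fits; taking the maximum is conservative (it inflates rather
than deflates null variance at small n). No numerical equivalence with any
specific DE package release is claimed or required. log2 fold changes use
normalized group means; when one mean is zero a pseudocount of 1 is added to
both and the gene is flagged. The screening filter uses raw P values (strict
P < 0.05, inclusive |log2FC| ≥ 0.5); a Benjamini-Hochberg column is emitted
for information only, since the downstream qPCR validation — not the screen —
controls the error rate in this design.

## Candidate reference cascade

Stage 1 removes group-dependent or rare miRNAs (P < 0.05, or pooled mean
TPM < 1); stage 2 removes miRNAs whose case/control mean-TPM ratio leaves
[0.75, 1.3]; stage 3 ranks survivors by coefficient of variation over **all**
samples (sample SD, n−1) and keeps the first 8 with pooled mean TPM > 50.
Where the published description does not say which mean the abundance cutoffs
use, the pooled mean over all samples was chosen (the ratio, by contrast,
explicitly compares group means); each stage's pass flag is retained for
audit. CV ties break by higher pooled mean, then id, so the selection is a
deterministic function of the data.

## Stability algorithms

All methods operate on Ct values; with amplification efficiency fixed at
E = 2 (no assay-specific calibration data being modelled), one cycle is one
log₂ unit of expression.

* **geNorm.** Relative quantities Q = E^(minCt − Ct); pairwise variation
  V_jk = sample SD over samples of log₂(Q_j/Q_k); M_j = mean over partners.
  The max-M gene is removed each round and M recomputed until two remain.
  The reported per-gene M is the value at its elimination round; the final
  pair shares one M (the algorithm cannot separate the last two), so both
  receive the best rank. At E = 2, V_jk is algebraically the sample SD of
  (Ct_k − Ct_j) — identical to the ΔCt method's pairwise SD — which the
  suite asserts to 1e-9 on random panels.
* **NormFinder.** On log-scale expression (−Ct), the gene×group mean table is
  decomposed into gene, group and interaction terms; the interaction d_ig is
  the intergroup deviation. Intragroup variances come from two-way residuals
  within each group with an explicit bias correction,
  σ̂²_ig = (u_ig − Ŝ_g/k²)·k/(k−2) with u the per-gene residual mean square
  and Ŝ the corrected total, truncated at zero (the residual step mixes
  genes, so the naive mean square is biased by the panel's other genes).
  d_ig is shrunk toward zero by γ²/(γ² + var(d_ig)), with γ² the
  between-gene variance of d̂ net of sampling noise (truncated at zero), and
  the stability value is the mean over groups of |shrunk d| plus its standard
  error. With a single group the intragroup-only variant (√σ̂²) is used and
  flagged. The implementation follows this model contract; exact numerical
  identity with the original add-in is not claimed, and the tests are
  behavioral (dominance of quiet genes, group-swap invariance, Monte-Carlo
  detection of a planted shifted assay).
* **BestKeeper.** SD[±CP] defaults to the mean absolute deviation of Ct from
  its arithmetic mean — the original tool's convention — with plain sample SD
  behind an option; CV[%CP] = SD/mean·100. The per-sample geometric-mean
  BestKeeper index and each assay's Pearson r against it are reported.
* **Comparative ΔCt.** Per gene, the arithmetic mean over partners of the
  sample SD of pairwise Ct differences, pairwise-complete with a minimum of
  two shared samples.

**Consensus.** Exactly the four statistics above are competition-ranked
(tied values share the minimum rank) and combined by geometric mean, sorted
ascending with ties broken by mean rank then id. This reproduces eight of the
nine published consensus values when applied to the published (rounded)
per-method statistics; the ninth (miR-532-5p, published 1.86) is not
recomputable because its published BestKeeper SD ties another gene's at 0.6
while the tool's unrounded values evidently differed — the recomputation
yields 1.68 and the discrepancy is documented rather than patched.

**Exclusions and final pick.** Assays with mean Ct > 33 (strict) are removed
before stability analysis. The final reference set takes the consensus top
four and iteratively drops the member with the highest mean Ct (lowest
expression) until three remain; Ct ties drop the worse-consensus member. The
geNorm V(n/n+1) series is computed as a diagnostic but deliberately not used
to choose the number of references — the three-reference convention is fixed
by design.

## Quantification

The multi-reference normalizer is the geometric mean of the references'
back-transformed quantities 2^-Ct, i.e. the arithmetic mean of their Cts;
ΔCt = Ct_target − normalizer, relative expression 2^-ΔCt, reported with
log10(2^-ΔCt) = −ΔCt·log10(2). A variant normalizer (geometric mean of the
raw Ct values) is available behind an option and differs negligibly over
narrow Ct ranges. Samples missing any reference Ct are dropped with a logged
warning rather than imputed — how undetected wells were handled in the
original cohort is not recorded, so this is a stated package choice; missing
target Cts propagate as missing.

## Rank tests and ROC

Mann-Whitney uses midranks, exact enumeration when the combined n ≤ 12 with
no ties, and otherwise the tie-corrected normal approximation without
continuity correction (the convention of common clinical statistics
packages). Kruskal-Wallis applies the standard tie correction with χ²_{k−1}
P values and reports per-group average ranks; the rank-sum identity
Σ n_g·R̄_g = N(N+1)/2 is asserted on every result. AUC is the Mann-Whitney
probability (ties ½), computed from midranks and verified against exhaustive
pair counting. The default SE is Hanley-McNeil's distribution-free formula
with DeLong's placement-value variance as an option; published SEs from
proprietary software are generally not bit-reproducible, so the reproducible
arithmetic is the CI construction AUC ± 1.96·SE (clipped to [0, 1]) and the
z test against AUC = 0.5. Scores are ΔCt with cases expected lower; the
orientation is explicit and never auto-flipped.

## Synthetic-data generator

The count generator emulates a detected-miRNA discovery matrix: per-gene
baselines log-normal(μ = 3.5, σ = 1.2) (median ≈ 33 counts with a long right
tail, the shape of a detected serum-miRNA panel), NB dispersion α = 0.05,
library-size factors log-normal(σ = 0.25) centred to geometric mean 1,
1608 genes of which 75 carry a ±1 log₂ planted effect (sign per gene), and
10 reference-like genes (no group effect, α ≤ 0.01, high abundance).
The Ct generator emulates the validation cohort: Gaussian Ct noise (SD 0.4
for reference assays, 1.0 for markers), case shifts of −1.5 and −0.7 cycles
for the two markers, and a 38-cycle detection limit above which readings are
missing. Randomness derives from one seed per config through
`SeedSequence` stream-splitting (library sizes and each gene/assay on
independent child streams keyed by index), so identical configs are
byte-identical and enlarging a panel never perturbs earlier features.

What the generator does **not** model: batch effects, hemolysis or other
pre-analytical artifacts, assay-specific amplification efficiencies,
inter-run qPCR calibration, correlated miRNA co-regulation, or read-level
sequence content. Passing recovery tests therefore demonstrates that the
estimators recover the generating model's planted structure at the study's
sample sizes — not that they are robust to those real-data artifacts.

## Numerical choices and degenerate inputs

Ties: competition ranking throughout the consensus; CV and drop-step ties
break deterministically (documented above); the geNorm elimination tie-break
removes the lexicographically last of the tied assays. Exact-test pmfs are
normalized in log space against the row maximum to avoid underflow.
All-zero genes get P = 1 and are flagged; an empty candidate shortlist is a
reported outcome with stage-wise attrition, not an exception; a panel whose
assays all exceed the Ct cutoff, a group with fewer than two samples, or
missing Cts inside geNorm/NormFinder raise labelled errors.

## Problem sizes used in the checks

The packaged checks run at desk scale by design: DE recovery on 500-gene
6+6 matrices, stability recovery on 6-assay 7+7 panels over 200 seeded
replicates, ROC calibration on 50/25 binormal cohorts over 500 replicates,
and the full synthetic pipeline at the 1608-gene default. Published
cohort-level numbers that depend on unavailable subject-level measurements
(the validation AUCs, the per-method stability statistics, the
clinicopathological P values) are anchored instead through their reproducible
arithmetic (consensus re-ranking, CI reconstruction, rank-sum identities) and
through parameter-recovery simulations at matched design sizes.

## Known limitations

* The NB dispersion trend is a two-parameter least-squares fit, adequate for
  screening but cruder than shrinkage estimators used by modern DE packages.
* NormFinder's variance decomposition assumes two groups of reasonable size;
  very small groups (n < 4) make the shrinkage aggressive.
* BestKeeper correlations require complete cases across the panel.
* The exact test enumerates all splits of a gene's total count; genes with
  totals in the millions dominate runtime (still linear per gene).
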