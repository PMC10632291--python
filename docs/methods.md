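# Methods

## Model and estimators

The population is assumed fully homozygous (doubled-haploid or
recombinant-inbred), so every marker locus carries one of two parental
alleles, coded x ∈ {−1, +1}. Line means follow the linear model

y = 1μ + Xβ + Zγ + Wδ + e,

with X the additive columns, Z pairwise products (aa epistasis), W triple
products (aaa epistasis) and e independent errors. With ±1 coding every
interaction column is itself a ±1 column, and the model is an ANOVA-style
factorial contrast parameterization: δ for a triple is half the difference
between the mean of lines with x₁x₂x₃ = +1 and those with −1.

Unweighted estimation is ordinary least squares, α̂ᵤ = (G′G)⁻¹G′y for
G = [1 X Z W] of full rank. Weighted estimation replaces the identity with
the diagonal matrix of empirical per-line replicate variances wᵢᵢ:
α̂𝓌 = (G′W⁻¹G)⁻¹G′W⁻¹y. The wᵢᵢ are treated as *relative* variances
only: coefficient covariances are (G′W⁻¹G)⁻¹ rescaled by the weighted
residual mean square, not by trusting the wᵢᵢ as absolute scales. Because a
line's sample mean and sample variance are independent under normality, the
estimated weights are independent of the errors in y and the weighted
estimator remains unbiased even with as few as 3 replicates per line.

Per-line variance fallbacks: lines with < 2 replicates (or zero sample
variance) receive the median of the available line variances; when no line
is replicated the fit falls back to unit weights with a warning, making the
weighted fit equal the unweighted one.

The total three-way effect (aaa₉ᵤ, aaa₉𝓌) is the plain sum of the triple
coefficients retained in the model. By default only triples with
coefficient p < 0.001 are counted (`total_aaa(..., "significant_only")`),
matching the convention of counting significant triples; `all_retained` is
available. Per-triple variance explained is
100·(RSS₋ₜ − RSS)/TSS, computed by two fits in the model's own weighting,
with TSS about the weighted mean.

## Phenotype-only estimation

aaaₚ = ½(L_max + L_min) − L̄ over line means. Rationale: in a homozygous
population the extreme lines tend to accumulate, respectively, the
increasing and decreasing alleles at all loci; additive and pairwise
contributions then cancel between the midrange and the mean, while
odd-order interaction structure shifts the mean relative to the midrange.
The significance test treats the estimator as a 1-df contrast with
coefficients ½ − 1/n on the two extreme lines and −1/n elsewhere:
SS = est²/Σ(cᵢ²/rᵢ) on 1 df against the pooled within-line mean square.
Because the extreme lines are *chosen from the data* and the contrast
variance formula treats them as fixed, the test is strongly conservative
under a pure-noise null (the midrange of n iid means has variance
≈ π²/(12·2·log n) of the single-mean variance, an order of magnitude below
the Σcᵢ² ≈ ½ the formula assumes); its null rejection rate at α = 0.05 is
essentially 0 rather than 0.05. It is reported as such, and a significant
result is correspondingly trustworthy. Ties for the extreme line go to the
first in line order; the estimate does not depend on that choice.

The number of effective factors uses the Wright-type form
k = (L_max − L_min)²/(8·V_g), V_g = var(line means) − MS_e/r̄ floored at 0;
k = 0 when V_g = 0. This is a documented variant: the /8 constant is the
classical F2-range calibration, and for DH populations (per-locus variance
a² rather than a²/2) it tends to *undercount* equal-effect loci by up to a
factor of two; validation is therefore by simulation recovery (k within ±1
of a planted 3-locus architecture), not by matching any published gene
count.

## Marker selection

Three deterministic stages on the unweighted line-mean response (weighting
is applied only to the final estimation, not to selection):

1. per linkage group: bidirectional stepwise AIC over the group's additive
   columns (Gaussian AIC = n·log(RSS/n) + 2k up to a constant; ties go to
   the lowest term index), then iterative backward elimination of selected
   markers whose coefficient fails a t test at α = 0.001 divided by the
   group's candidate count (Bonferroni per stage, configurable off). The
   filter drops one worst coefficient at a time and refits: tightly linked
   co-selected markers share signal, and a simultaneous cut would discard
   them all, true QTL included.
2. pooled: the survivors of all groups compete in one stepwise-AIC +
   backward-elimination pass, Bonferroni over the pooled candidate count.
3. interactions: pair and triple product columns are built only over the
   surviving additive loci (the hierarchy assumption: interactions are
   displayed only by loci with significant additive effects). Stepwise AIC
   runs over pairs and triples jointly in one pool while the additive terms
   are protected from removal; retained triples must additionally reach
   p < 0.001 (flat, not Bonferroni-divided). A `hierarchical` option
   restricts triples to those whose three constituent pairs were retained,
   for sensitivity analysis.

Numerical safeguards: stepwise AIC floors the RSS at 1e−12·‖y‖² so a
numerically perfect fit cannot keep "improving"; aliased design columns
(singular value below 1e−8 of the largest, e.g. duplicate markers, whose
pair column x·x = 1 collides with the intercept) are dropped greedily in
term order and logged before any fit.

## Imputation

Missing genotypes are imputed per line and linkage group from the nearest
non-missing flanking markers under the two-state Markov chain of a DH
gamete: P(x = s | left a, right b) ∝ P(a→s over r₁)·P(s→b over r₂), with
recombination fractions from the Haldane map function
r = ½(1 − e^(−2d/100)) by default (no interference; Kosambi selectable).
Single-flank entries use the one-leg conditional a·(1 − 2r); entries with
no informative flank become 0, the no-information expectation. Imputed
values are left real-valued in [−1, 1] — this preserves expectations and
avoids bias in the downstream regressions — with an optional rounding to
hard ±1 calls (ties → +1). This is deliberately not a full multipoint HMM:
flanking information captures almost all of the chain's information when
missingness is scattered, which is the regime the masking option simulates.

## Simulator

`simulate_genotypes` draws each linkage group as a two-state Markov chain:
first marker ±1 with probability ½, subsequent markers flipping with the
Haldane recombination fraction of the inter-marker distance; groups and
lines independent. `simulate_phenotypes` builds line genetic values
μ + Σaᵢxᵢ + Σaa·xx + Σaaa·xxx and adds replicate noise with per-line SDs
that are either constant or log-normal across lines (median `noise_sd`,
log-SD `noise_spread`) — the latter creates the heteroscedasticity that
per-line weights exploit. Everything is reproducible from a seed.

What the generator emulates: the study-scale geometry (126 lines; the
default map is the study's map scaled down to 5 groups × 40 markers at
~2.6 cM spacing, preserving ~100 cM groups), replicate structure, and
variance heterogeneity between lines. What it does not emulate: marker
ascertainment and clustering of a real genotyping platform, segregation
distortion, genotyping error, multi-trait correlation, and
genotype×environment structure. Passing tests therefore demonstrate
estimator correctness under the stated generative model, not robustness to
those real-data features.

### Monte-Carlo harness and the recovery definition

`monte_carlo_compare` runs, per replicate, the full pipeline (simulate →
optional mask + impute → select → fit both ways) *and* a fit of the
true-model design. The two tracks answer different questions:

- selection performance: a true triple counts as **recovered** when a
  retained triple localizes each true QTL within ±10 cM on its linkage
  group (bijectively). Exact-marker identity is not a usable criterion at
  realistic map density: adjacent markers 2.6 cM apart differ in only ~3 of
  126 lines, and in the per-group selection fits the unmodeled triple
  (δ = 5 ⇒ SD 5 of genetic "noise") plus the other groups' additive
  variance reduce the neighbour-vs-true discrimination to z ≈ 1, so the
  exact marker wins only ~85% of each flank comparison (measured
  exact-recovery ≈ 0.12, windowed ≈ 0.82 under the default scenario).
  False triples are those not matching any true triple under the window.
- estimator performance: bias, MSE and variance explained of the aaa
  estimators are computed on the true design, so they are not confounded
  with the selector's localization error (which would attenuate estimates
  by the correlation ≈ 0.9 between a mislocalized and the true triple
  column) nor with winner's-curse conditioning on exact selection.

Default scenarios (sizes chosen to mirror the study's geometry and run on
a desk machine): 126 lines, 5 groups × 40 markers over 100 cM each, three
additive QTLs of effect 5 on distinct groups, one triple δ = 5, 3
replicates; replicate SD 0.5 for the low-noise recovery condition, median
SD 2.0 with log-normal spread 1.15 (quartile ratio ≈ 4.7, line variances
spanning > 2 orders of magnitude) for the heteroscedastic condition; 200
Monte-Carlo replicates (500 for the null). These are also the sizes
`scripts/acceptance.py` uses.

## Known limitations

- Selection inference is conditional: reported p-values do not account for
  the stepwise search, so they are optimistic for the *selected* terms
  (standard for this protocol; the Bonferroni step thresholds compensate in
  practice, as the null false-triple rate ≈ 0 shows).
- The aaaₚ F test is conservative (see above); a calibrated test would need
  the null distribution of the data-chosen midrange.
- Heterozygotes are out of scope by design (homozygous populations only),
  as are dominance terms, G×E, and kinship adjustment.
- The effective-factors count is a rough lower-bound-style diagnostic, not
  an estimator of QTL number.
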