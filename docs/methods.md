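# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical decisions a maintainer would want written down.

## Pooled read-count model

For pool *i* and site *s* the generator draws

* depth *d* ~ Poisson(μ), μ = 43,654 by default (the reference design's
  mean per-pool coverage);
* per-sample contribution weights *w* ~ lognormal with mean 1 and CV
  *c* = 0.4, constant across sites within a pool (one aliquot per
  sample); the true alternate fraction is the weighted carrier allele
  fraction p₀ = Σ w·(copies/2) / Σ w;
* an amplification bias *b* = 1.08 and base error ε = 0.001 give
  p = clip(b·p₀ + ε(1 − 2p₀), 0, 1);
* alternate reads ~ beta-binomial(d, p, ρ) with ρ = 10⁻⁴ (binomial when
  ρ = 0); each allele's reads split between strands as Binomial(½).

Why these defaults: a single heterozygote in a pool of 50 has
p₀ = 1/100 in expectation regardless of the weights (the weight ratio is
mean-one), so the observed elevation of true-positive VAF above 1% cannot
come from unequal pooling alone; it is modelled as a small constant
amplification advantage of the variant allele, set so the expected called
VAF is 1.08 × 1% + ε ≈ 1.18%, the level the assay actually exhibits.
The contribution CV of 0.4 alone reproduces a true-positive VAF spread of
≈0.4%, matching the observed ±0.39%; read-sampling overdispersion is
therefore kept small (ρ = 10⁻⁴) — at ρ = 0.01 the VAF SD would triple
and no longer resemble the assay.

False positives are injected as 17 error-only sites, each manifesting in
one randomly chosen pool as an elevated per-site error rate, lognormal
with median 5.5ε and log-SD 0.12. This reproduces the observed behaviour
of a localized library artifact: most artifact VAFs land between the 0.5%
screening threshold and the 0.6% recalibrated cutoff, a handful above it.
The real error process behind such calls is unknown; this injection is a
stand-in that gives the calibration stage both label classes, not a claim
about the chemistry.

## Candidate calling

A pool×site passes when all of: VAF ≥ `vaf_min` (default 0.005, the
screening threshold used ahead of recalibration; the raw caller criterion
of 0.0005 is available by configuration), depth ≥ 100, one-sided exact
binomial tail P(X ≥ alt | depth, ε₀ = 0.001) < 0.05, and — when the
strand filter is on — at least one alternate read per strand with a
minor-strand fraction ≥ 0.1. The binomial tail is computed exactly at
every depth via the regularized incomplete beta function; no normal
approximation is used, since the exact form is stable and as fast. The
VAF denominator is ref+alt reads; zero-depth sites yield flagged,
non-passing records. Coordinates are 1-based, VCF convention; SNVs and
short indels are treated identically as alt-allele counts.

## Calibration

Validation records (the capillary-sequencing oracle is perfect by
default; a miss rate is configurable) label each passing call TP iff any
pool member is a confirmed carrier at the site. The AUC is the
two-sample rank statistic P(VAF_TP > VAF_FP) + ½P(tie), which equals the
trapezoidal integral of the empirical ROC; both are computed and the
identity is asserted in tests. The recalibrated cutoff is the largest
multiple of the grid step (default 10⁻⁴) not exceeding the smallest TP
VAF, with inclusive (≥) comparison, so every validated TP is retained by
construction. Because validation labels exist only for calls, the
operative precision figure is TP/(TP+FP) among retained calls
(`ppv_percent`); the classical specificity (fraction of FP calls removed)
is reported alongside, clearly labelled. Concordance between two
per-individual carrier call sets is |A∩B| / |A∪B| restricted to the
overlap of sequenced individuals.

## Carrier resolution, exclusions, prevalence

The exclusion ledger applies, in fixed order: (1) missing-identifier
rows; (2) duplicated aliquots; (3) unsequenced members of sibling sets
spanning the sequenced-set boundary; (4) one-per-multiplet within the
sequenced set, keeping the lexicographically lowest id (the tie-break is
a package choice; any deterministic rule conserves the counts). The
ledger records each step and conservation is asserted.

Prevalence counts each carrier once, in the most severe class under
cLoF > pLoF > GoF > WT-like (the ordering matters only for
multi-variant carriers, which the reference data did not contain).
Intervals are exact Clopper–Pearson at 95%. Minor allele frequency is
allele copies / 2N as a percent rounded to four decimals; with N = 5724
a two-carrier variant gives 0.0175% (the reference variant table prints
0.0173% for two of its two-carrier rows — an internal inconsistency of
that table; the arithmetic here is kept consistent).

## Dose-response classification

"4-point"/"3-point sigmoidal" fits are implemented as four- and
three-parameter logistic models in log₁₀ dose (the three-parameter model
fixes the Hill slope at 1). Fitting is multi-start Levenberg–Marquardt
with logEC₅₀ starts on a unit grid spanning the dose range ±2 decades;
parameter SEs come from the Gauss–Newton covariance. Data whose per-dose
mean response spans less than 10 %WT follow the complete-LoF path: no
curve fit, E<sub>max</sub> read from the top-dose responses, comparison
to WT by t-test at the top dose. An EC₅₀ fitted more than two decades
outside the dose range is flagged unreliable.

Variant-vs-WT comparison uses the extra-sum-of-squares F-test: the full
model fits each curve separately; the reduced model shares one parameter
(E<sub>max</sub> or logEC₅₀) across curves in a joint fit;
F = ((SS_r − SS_f)/(df_r − df_f)) / (SS_f/df_f). For the coupling assay,
replicate-level fits are compared with two-sided t-tests instead. The
kinetic readout is reduced to a trapezoidal area above the mean baseline,
clipped at zero below baseline by default (coupling cannot be negative;
the clip is a flag).

Classification defaults: cLoF if flat or E<sub>max</sub> < 20 %WT; pLoF
if E<sub>max</sub> is significantly below WT or EC₅₀ significantly
right-shifted at α = 0.05; GoF for the opposite directions; otherwise
WT-like; conflicting directions are flagged ambiguous and the more severe
label reported. The quantitative thresholds used in the original
functional annotations are not public; these defaults are explicit,
configurable assumptions.

## Growth trajectories and the two-level model

The generating model and the fitted model share one mean structure: a
linear spline parameterised as per-interval slopes (term *j* is the time
accrued inside interval *j*), so coefficients are units/year and an
age-*a* carrier gap is the inner product of the carrier terms with
(1, basis(a)). Knots: BMI 3.5/5/8/15 y (modelled from 18 months, where
the intercept anchors at 16.84 kg/m²), height 5/15 y (from 18 months,
81.90 cm), weight 1/8/15 y (from birth, 3.44 kg) — the reference knot
placements. Carrier offsets: BMI slopes constant at 4.84/16.5 per year
(an 18-y gap of 4.84 kg/m², accruing smoothly with age as observed);
weight slope offsets 0.5 / 0.84 / 1.33 / 0.69 kg/y — the middle two are
the reference's printed interval estimates, the flanks chosen so the 18-y
gap is 17.76 kg. Sex offsets and population slopes are plausible
growth-curve values; they affect nothing downstream except realism of the
fitted nuisance terms. Individual heterogeneity is a random intercept
plus random linear age slope (SDs 1.1 and 0.15 for BMI, correlation
0.25, residual 0.8 kg/m²), giving an 18-y BMI SD ≈ 3.2. Missingness is
at random with per-occasion presence probabilities declining from 0.9 at
18 months to 0.6 at 18 y, emulating cohort attrition.

Estimation is REML. The default engine profiles β and σ² out of the
restricted likelihood and optimises over the log-Cholesky factor of the
scaled level-2 covariance (Nelder–Mead, xatol 10⁻⁴, fatol 10⁻⁶ on the
log-likelihood); per-group Woodbury solves are batched over groups of
equal size, so a cohort-scale fit (5724 individuals, ~40k observations)
takes well under a second. statsmodels `MixedLM` is available as
`engine="statsmodels"` and the two engines are asserted to agree in the
test-suite; the specialised engine exists because fitting hundreds of
replicate cohorts for calibration checks is otherwise impractical. The
best-so-far restricted log-likelihood trajectory is recorded and asserted
monotone. A level-2 covariance collapsing to zero is handled by the
boundary (the `boundary` flag on the fit); warm-starting from a previous
replicate's solution is supported.

The PRS is a standard Gaussian score; its coupling to a trait is a level
shift of `prs_beta` trait units per SD, and `prs_beta_for_r2` solves the
loading for a target variance explained (the pipeline default dials 10%
for BMI at 18 y, which also makes the carrier effect roughly double the
top-decile-vs-rest score contrast, the configured relationship between
the rare and common variant signals).

## What the generators do not emulate

No read-level artefacts (alignment, duplicates, base-quality structure),
no haplotypes or linkage, no population structure or ancestry, no
genotype-by-age interaction beyond the linear spline, no informative
missingness, and the false-positive process is a stand-in (above).
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated models, and calibration (bias, interval
coverage, AUC behaviour) under realistic magnitudes — not robustness to
real-data artefacts outside those models.

## Problem sizes used by the test-suite

Calibration suites run at the reference design scale where that matters:
the ROC behaviour suite uses 200 replicates of the full 120-pool,
43,654× design; the mixed-model recovery suite uses 200 replicate
cohorts of 5724 individuals with 17 LoF carriers for each of BMI and
weight. Unit tests use smaller cohorts (tens to hundreds of individuals)
and the bundled three-pool fixture set, all generated from seeds at test
time. The F-test null-uniformity check uses 150 simulated null pairs and
the power check 60 pairs; these sizes keep the default `pytest` run
around five minutes on one CPU.
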