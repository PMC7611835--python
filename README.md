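# poolvar

**Pooled-sequencing rare-variant discovery, calibration and cohort
phenotype association.**

`poolvar` implements the full statistical arc of a pooled resequencing
study of a single gene in a birth cohort — the design used to measure the
population prevalence of functionally impaired melanocortin-4-receptor
(MC4R) variants and their effect on growth. DNA from thousands of
participants is sequenced in pools (e.g. 120 pools of 50 diploid samples
at ~43,654× depth), so a single heterozygous carrier appears as a
low-frequency allele signal; candidate calls are validated per individual,
the operating threshold is recalibrated from the validation labels,
carriers are resolved and counted, each variant's pharmacology is
classified *in vitro*, and carrier status is related to longitudinal
anthropometry and to a common-variant polygenic score. The package is
aimed at statistical geneticists and sequencing-methods developers who
want a tested, reusable, fully synthetic-data-driven implementation of
that pipeline: every input the analysis consumes can be generated from a
seed with the noise structure the real assay exhibits.

## The statistics at the core

* **Pooled allele signal.** In an equimolar pool of *P* diploids, *n*
  heterozygous carriers contribute an expected variant allele fraction
  (VAF) of *n*/(2*P*) — 1% for one carrier in a pool of 50. The
  generator models unequal DNA contribution (lognormal weights),
  amplification bias, base error ε and beta-binomial read overdispersion,
  reproducing the observed mean true-positive VAF of ~1.18% against the
  1% theoretical value.
* **Candidate calling.** A pool×site passes when VAF ≥ threshold,
  coverage ≥ 100, a one-sided exact binomial tail
  P(X ≥ alt | depth, ε₀) falls below α, and alternate reads appear
  adequately on both strands (90/10-style rule).
* **Validation-driven recalibration.** Calls are labelled TP/FP from
  per-individual capillary sequencing; the VAF threshold is re-chosen as
  the largest grid value retaining *every* TP, and discrimination is
  summarised by the rank-statistic AUC (equal to trapezoidal ROC
  integration; checked against each other).
* **Prevalence.** Carriers are counted once each in their most severe
  functional class, with exact Clopper–Pearson intervals; loss-of-function
  (LoF = partial + complete) prevalence is reported as a percentage and a
  "1 in *k*" headline.
* **Pharmacological classification.** Four-parameter (cAMP) and
  three-parameter (β-arrestin-2 coupling, after AUC-above-baseline
  reduction) logistic dose-response fits; extra-sum-of-squares F-tests (or
  replicate-level t-tests) on E<sub>max</sub> and logEC<sub>50</sub>
  against wild type decide cLoF / pLoF / WT-like / GoF.
* **Growth models.** Age-specific sex-adjusted linear regression, and a
  two-level (occasion within individual) linear-spline mixed model with
  carrier×spline and sex×spline interactions, estimated by REML. The
  spline basis is parameterised as per-interval slopes so coefficients
  read as units/year; the carrier trajectory gap at any age is a linear
  combination of the carrier terms.
* **Polygenic-score comparison.** Top-decile vs lower-90% score contrast,
  PRS-adjusted carrier effects, and variance explained (R²).

## Worked example

Run the whole pipeline at the reference design scale (5993 samples, 120
pools of 50, mean depth 43,654×) from one seed:

```bash
poolvar run-all --seed 20 --out runs/demo
```

or equivalently from Python:

```python
from poolvar import RunConfig, run_end_to_end
report = run_end_to_end(RunConfig(seed=20), "runs/demo")
```

The stage log and headline report for this seed:

```
[poolvar +   0.1s] simulated pileups for 120 pools x 42 sites
[poolvar +   0.2s] 47 passing candidate calls of 5040 records
[poolvar +   0.2s] calibrated VAF cutoff 0.0053
[poolvar +   6.9s] classified 25 confirmed variants
[poolvar +   7.0s] analysis set 5724; LoF carriers 19 (0.33%)
[poolvar +   8.8s] BMI: 18y MLM gap 6.26 (se 0.75)
[poolvar +  10.2s] weight: 18y MLM gap 17.87 (se 2.56)
```

Reading the numbers: of 5040 pool×site records, 47 passed the 0.5%
screening VAF with coverage, significance and strand criteria; validation
labelled 37 TP and 10 FP, and the recalibrated cutoff (0.53%, the largest
grid value keeping every TP) removed one FP (AUC 0.935 in this
replicate). After the exclusion ledger (missing identifiers, duplicated
aliquots, one-per-sibling-set) the analysis set is 5724, in which 19
detected LoF carriers give a prevalence of 0.33% ≈ 1 in 301 (the
generating value was 17 carriers, 0.30%, 1 in 337 — one seed's binomial
noise). The two-level spline model estimates an 18-year carrier gap of
6.26 kg/m² BMI (generating value 4.84; 17-carrier designs are noisy, se
0.75) and 17.87 kg weight (generating value 17.76). The report also
contains the polygenic-score comparison: this seed gives a top-decile PRS
contrast of 1.84 kg/m² against the carrier effect of 5.78 — the
configured ~2:1 relationship — with the PRS explaining 8.4% of BMI
variance at 18 y (configured 10%) versus 1.2% for carrier status.

Every intermediate (pileups, candidate calls, labelled calls, ROC table,
carriers, prevalence table, per-trait phenotypes, model reports) is
written under the output directory as TSV/JSON/VCF.

## Layout

```
src/poolvar/
  synthetic_cohort.py   # cohort, pools, pileups, Sanger oracle, trajectories, assays, PRS
  pool_caller.py        # screening criteria and exact binomial significance
  calibration.py        # TP/FP labelling, ROC/AUC, cutoff recalibration, concordance
  carrier_resolution.py # carrier resolution, exclusion ledger, prevalence, MAF
  pharm_class.py        # dose-response fits, F/t tests, functional classification
  growth_models.py      # spline basis, age-specific OLS, two-level REML engine
  prs_compare.py        # decile grouping, R^2, adjusted models
  cli.py                # RunConfig, end-to-end orchestration, click CLI
docs/methods.md         # modelling assumptions, defaults and limitations
```
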