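# Methods

## Assay and data model

The pipeline models a 96-well organoid drug screen: each PDO line is tested
against a panel of drugs at three concentrations (low, medium, high), each
condition in triplicate wells, with solvent-only control wells on every
plate, and end-point ATP luminescence as the viability readout.  The packaged
default panel carries 25 drugs; each drug's dose triple is uniformly spaced
in log10 molarity and was calibrated to bracket the drug's average IC50
within the physiologically achievable range.  A full screen
(25 drugs × 3 doses × 3 replicates = 225 condition wells) exceeds the 60
usable center wells of one plate, so the canonical raw format is a long CSV
(one row per well) spanning multiple plates; an 8×12 plate-map converter is
a convenience on top.  Edge wells (rows A/H, columns 1/12) trigger a warning
but are not rejected — the center-well convention guards against evaporation
artifacts, not validity.

## Normalization and QC

Per condition, the triplicate mean and standard error are computed on
normalized values: each well's luminescence divided by the mean of the
control wells in scope, ×100 (percent relative viability).  Controls are
pooled **per plate** by default because absolute luminescence drifts between
plates (reader gain, reagent lot, seeding density); per-screen pooling is a
config option.  Negative normalized values are clamped to 0 (areas must not
go negative) while values above 100% are kept — growth stimulation is real
signal.

A condition is excluded when the SEM of its normalized wells exceeds
12 percentage points, **strictly**: SEM = 12.0 exactly is retained.  The
threshold is expressed in percent-of-control points because the rule is
applied after normalization.  Exclusion is terminal — no imputation; a
missing level voids the whole PDO × drug profile ("not tested"), and re-runs
enter the pipeline as new raw data.

## Scoring

With `AUC(v)` the trapezoidal area under the 3-point viability curve divided
by the full-response rectangle (no-effect value × x-range):

* AUC score = `AUC(cohort mean profile) / max(AUC(v), 0.01)`
* sensitivity score = `1 − AUC(v)`
* final score = sum of the two; hit ⇔ final score > threshold (strict).

Numerical and design choices, with rationale:

* **x-axis = concentration index (0, 1, 2).**  Every default-panel triple is
  uniformly spaced in log10 M, so index spacing equals log-molar spacing up
  to a per-drug constant that cancels in both the AUC ratio and the
  normalized sensitivity score; index spacing additionally tolerates panels
  with non-uniform triples.  A `log10M` spacing mode exists and provably
  gives identical scores on uniformly spaced panels (tested to 1e-12).
* **Trapezoid rule.**  The standard discrete-AUC choice; being linear in the
  viabilities it admits an exact oracle (AUC of the mean curve = mean of the
  member AUCs) that the tests assert on random cohorts.
* **AUC floor 0.01.**  A total-kill profile has AUC 0; flooring the
  denominator keeps the AUC score finite and preserves monotonicity (more
  killing never lowers a score).  The floor is configurable in (0, 0.1].
* **Cohort reference includes the scored PDO.**  The reference is the plain
  average over the lines the cohort was built from, each of which is then
  scored against it.  A leave-one-out switch exists for scoring prospective
  lines against a frozen reference.
* **Missing pairs.**  Cohort averages are taken over available profiles per
  drug; a drug with fewer than 2 available profiles cannot anchor a relative
  score and is left all-missing with a warning.
* **Hit threshold.**  Fixed at 1.9 by default (the third quartile of a
  pooled pilot-cohort score distribution), so a single new PDO can be scored
  without re-deriving quartiles.  `cohort_q3` mode recomputes the threshold
  as the 75th percentile of the pooled present scores using the
  linear-interpolation quantile rule (the common inclusive spreadsheet
  method), making thresholds reproducible from any score matrix.  Ties at
  the threshold are not hits (strict `>`).
* **Units.**  All scores are invariant to expressing viability as fractions
  instead of percent, provided the `full_scale` setting matches (100 vs 1).

Useful identities the test suite pins down: a PDO identical to the cohort
average scores exactly `1 + its sensitivity score`; the per-drug mean of AUC
scores is ≥ 1 (AM–HM inequality); sensitivity score ≤ 1 always.

## Cohort analytics

* **Heterogeneity** per drug = sample SD (n−1) of present final scores;
  undefined (NaN, with warning) below 2 scores.
* **Drug–drug correlation**: pairwise-complete Pearson over PDOs scored for
  both drugs, requiring ≥ 3 complete pairs; the complete-pair count matrix is
  reported so thin correlations can be discounted.  Clustering is
  hierarchical with average linkage on the 1 − r distance (undefined
  distances set to the maximum, 2.0, so sparse matrices still cluster);
  linkage is configurable since only the correlation measure, not the
  linkage, is canonical for this assay.
* **Group comparisons** (e.g. hits per PDO by tumor origin) use Welch's
  unequal-variance t-test implemented from the closed-form statistic and
  Welch–Satterthwaite degrees of freedom, two-tailed.  It is validated
  against SciPy's independent implementation to 1e-10; zero-variance
  degeneracies are defined explicitly (equal means → t=0, p=1).  No
  multiple-testing correction is applied — the readouts are single planned
  comparisons.

## Clinical concordance

Responder = PR or SD (clinical benefit) by default; a strict mode counts PR
only.  The 2×2 table orients "positive" = PDO-sensitive ∧ responder, and the
four metrics are percentages with zero-denominator cases returned as
`None` and listed in `undefined` — never silently 0.  Records whose
PDO × drug score is missing are skipped with a warning.  Combination
regimens are represented by their single panel drug (e.g. an
oxaliplatin-based doublet maps to oxaliplatin); combination scoring is out
of scope.

## Synthetic screens

The generator emulates what the pipeline assumes about real screens:

* **Latent pharmacology.**  Each PDO × drug pair draws a latent log10 IC50
  from a normal distribution centred on the drug's **medium** panel dose
  (the panel was calibrated so the doses bracket the average IC50) with SD
  0.5 log10 units — a realistic inter-patient spread for ex vivo
  chemosensitivity.  Viability follows a 3-parameter log-logistic curve,
  Hill slope 1, residual viability `e_inf` = 0.1 (most cytotoxics leave a
  resistant fraction at saturating dose).
* **Plates and noise.**  Conditions are packed triplicate-wise into the 60
  center wells of sequential per-PDO plates, each with 6 solvent controls at
  a 10,000 RLU control scale.  Well noise is multiplicative Gaussian with
  CV 0.08 (typical plate-reader + seeding variability), truncated at −1;
  a lognormal mode is available.
* **Degradations.**  Pairs go missing uniformly at random (spiked pairs
  never do).  Deliberately degraded triplicates receive a fixed ±spread
  offset pattern scaled so the injected SEM equals a configured value
  (default 30 points).  A Gaussian noise inflation would make the *sample*
  SEM of an n=3 triplicate highly dispersed (chi with 2 df), so even a true
  SEM at twice the threshold would escape exclusion ~20% of the time; the
  deterministic pattern makes the injected SEM itself deterministic, which
  is the property a QC-sensitivity check needs.
* **Clinical model.**  One record per selected PDO; spiked pairs respond
  (PR or SD, evenly split) with one probability, unspiked with another.

What passing synthetic tests does **not** show: the generator has no spatial
plate effects (edge gradients, drift within a run), no correlation between
drugs beyond the shared curve family, no heteroscedastic viability floor
noise, and no biological covariates (passage number, stroma, growth-rate
confounding).  Conclusions about those aspects of real data are outside what
this test bed can support.

## Problem sizes

The validation suite runs at desk scale, chosen to keep the full chain
exercised with comfortable statistical margins: parameter recovery uses 20
seeds × 24 PDOs × 25 drugs with 20 spiked pairs at a −1.5 log10 IC50 shift
(400 spiked pairs total; ≥ 90% must rank above their drug's cohort median);
QC sensitivity uses 10 seeds × 8 PDOs with 10% degraded triplicates at an
injected SEM of 24 points (twice the threshold; ≥ 95% must be excluded);
oracle checks use 1,000 random cohorts (trapezoid linearity, 1e-12) and 100
random sample pairs (Welch, 1e-10).  The acceptance script mirrors these
sizes and completes in seconds.

## Known limitations

* Three-point dose curves cannot distinguish potency from slope; the scores
  are rank tools, not IC50 estimates.
* The AUC score is cohort-relative: adding PDOs to the reference changes
  historical scores unless the reference is frozen (use leave-one-out /
  stored references for prospective use).
* The hit threshold is a quartile of a particular pooled cohort; it is a
  convention, not a biologically derived cut-off.
* Concordance metrics on small matched cohorts (n ≈ 8) carry wide binomial
  uncertainty; the pipeline reports the point metrics only.
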