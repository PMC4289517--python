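# Methods

`metabodrift` implements the computational core of a large multi-batch
untargeted metabolomics campaign: simulation of raw peak-area studies with
known ground truth, pooled-QC-based drift correction (QC-RLSC), batch
integration, quality-assurance filtering, univariate and two-way ANOVA
statistics, bootstrap consensus feature selection with Borda-count
aggregation, and an empirical sample-size study. This note records the
models, the defaults and why, and the design choices made where the design
was genuinely open.

## The measurement model

A long chromatography–MS campaign measures each serum sample once, spread
over batches of runs acquired days or months apart. The observed peak area
of feature *f* at injection *i* factorizes multiplicatively:

    raw[i, f] = truth[i, f] · drift[i, f] · noise[i, f]

* `truth` — the biological abundance: a fixed pooled composition for every
  QC injection (pooled QCs are biologically identical, so their only
  variance is technical), or the subject's abundance
  `baseline_f · exp(σ_bio z + δ)`, log-normal across subjects with planted
  covariate shifts δ.
* `drift` — a per-feature, per-run smooth positive curve times a per-batch
  sensitivity step:
  `step_fb · exp(−λ(pos−1)) · (1 + a·sin(2π·pos/P))`. The exponential term
  models injection-order signal attenuation (λ is parameterized by the
  terminal retention, drawn per feature); the low-frequency sinusoid adds
  non-monotone wander; the log-normal step models between-batch
  sensitivity changes.
* `noise` — i.i.d. log-normal technical error on every injection.

Missingness combines left-censoring at a per-feature detection quantile
(MNAR, the dominant mechanism in peak tables) with a small
missing-completely-at-random rate. The generator returns the full
decomposition as ground truth, so `truth · drift · noise` masked by the
missingness mask reproduces the emitted study bit-exactly under the
generating seed.

### Generator defaults

| parameter | default | rationale |
|---|---|---|
| terminal attenuation | U(0, 0.4) per feature | up to 40 % signal loss over a run, the scale at which correction becomes necessary |
| sinusoid amplitude / period | U(0, 0.1), U(0.5, 2)·run length | mild non-monotone wander |
| batch step (log-SD) | 0.10 | ~10 % between-batch sensitivity changes |
| technical CV | 0.05 | pooled-QC replicate scatter of a well-behaved platform |
| biological CV | 0.45 | inter-subject relative SDs of serum features cluster in the tens of percent; 45 % also keeps the biological-to-technical variance ratio (~90) in the regime where corrected values can track true abundances at r > 0.99 — at CV_bio ≤ 30 % that correlation is unattainable for *any* corrector because technical noise alone caps it near 0.986 |
| MNAR quantile / MCAR rate | 0.02 / 0.01 | low single-digit missingness, concentrated in low-intensity cells |
| conditioning injections | 10 (UPLC), 5 (GC) per run | column equilibration block |
| QC interval | every 5th injection | standard pooled-QC cadence |

The cohort generator draws each continuous demographic (age, BMI, SBP,
DBP, five clinical-chemistry analytes) from a two-piece normal with each
half truncated at the stated physiological bounds; the half-scales are
calibrated numerically (Brent root-finding) so the *truncated*
distribution's median and quartiles equal the published cohort
calibration exactly (age 48.0, IQR 40–60; BMI 25.63, IQR 23.20–28.71;
SBP 125; DBP 76; male fraction 701/1191; smoking 502:163:176).
Marginals are independent by default — only marginal summaries are
published — with an optional Gaussian-copula hook for users who want,
e.g., corr(SBP, DBP) > 0. SBP > DBP is enforced per subject by paired
rejection.

What the generator does *not* emulate: retention-time drift and
mis-alignment, correlated metabolite panels (features are independent
given the planted effects), heteroscedastic technical error, adduct or
fragment degeneracy, and batch-specific feature detection differences
beyond what missingness induces. Passing tests therefore demonstrate that
the algorithms behave as specified under the stated error model, not that
any specific real-data feature count or F statistic is reproduced.

## QC-RLSC signal correction

For each feature and analytical run, a robust LOESS (tricube weights,
local linear fit) is regressed through the pooled-QC areas versus
injection order; conditioning QCs equilibrate the column and never enter
the fit or any statistic. The LOESS span is selected per feature by
leave-one-out cross-validation over the grid {0.3, 0.5, 0.75, 1.0}
(non-robust fits during CV), followed by two robustifying iterations —
skipped when residuals are numerically zero, where the reweighting is
undefined. A natural cubic spline interpolates the fitted values to every
injection position; beyond the terminal QCs the curve is held constant to
avoid spline blow-up at the run edges. All areas of the run are *divided*
by the curve (the multiplicative model above makes division, not
subtraction, the coherent operation), putting every batch on a common
normalized scale near 1. A feature with fewer than 4 usable QC points in
a run is flagged uncorrectable and set missing for that run; a fitted
curve that is anywhere non-positive falls back to the constant global
median of the run's QC areas and is flagged.

Integration concatenates the normalized batches — features matched across
batches by m/z (ppm) and retention-time window for UPLC, nearest-m/z rule
on ambiguity, or by library identity for GC — and un-normalizes each
merged feature by the median of its per-batch median raw QC areas,
restoring an interpretable intensity scale. On drift-free noise-free data
the constant curve cancels exactly against this median, so
correct → integrate is the identity.

Residual error after correction has two parts: the irreducible technical
CV, and curve-estimation error ≈ σ_tech/√(effective QC window) (~2–3 %
at the every-5th cadence). A sinusoidal drift component with period below
about one run length cannot be tracked from QCs every 5 positions by any
estimator (Nyquist-style limit); the generator's default periods stay at
or above half a run length, and the recovery analyses use ≥ 1 run length.

## Filters

Order: (1) post-correction QC RSD (sample SD, n−1) must not exceed the
platform tolerance — 20 % for UPLC–MS, 30 % for GC–MS; (2) presence in at
least 80 % of subject samples (≥ 80 % retained); (3) the information
filter removes features whose inter-subject RSD / QC RSD ratio is
strictly below 1.5 — when biological scatter is commensurate with
technical scatter the feature carries no usable biology. A zero QC RSD
yields an infinite ratio and the feature is retained (logged). Every
removed feature carries exactly one primary reason code, and all three
filters are idempotent.

## Statistics

Missing cells (≤ 20 % per feature by this stage) are imputed with the
feature mean, then each feature is autoscaled (mean-centred, unit sample
variance). Group screens are rank-based — Mann–Whitney U for two groups
(exact p for small tie-free samples, tie-corrected normal approximation
otherwise), Kruskal–Wallis beyond — so p-values are invariant under
monotone transforms. No multiple-testing correction is applied by
default; a Benjamini–Hochberg flag exists.

Two-way ANOVA uses an OLS fit with Type II sums of squares — the standard
choice for unbalanced observational designs when main effects are
interpreted alongside tested interactions; on balanced data Type II
coincides with sequential SS, which the tests exploit as a cross-check.
Group boundaries for the clinical hypotheses: age bins [min,40), [40,50),
[50,65), [65,max] (binary contrast <50 vs >64); BMI <25 vs >30, middle
excluded; systolic BP 90–120 (normal) vs >140 (hypertensive), middle
excluded; smoking non/ex/current. Tukey's HSD uses the exact studentized
range distribution, so for two groups its adjusted p equals the pooled
t-test p; comparisons "independent of" a second factor are performed on
data collapsed over that factor.

Correlation maps are pairwise-complete Pearson matrices ordered by
average-linkage hierarchical clustering on the 1 − |r| distance (the
linkage is a documented, configurable choice; the clustering method
itself is fixed). Square feature–feature maps support extraction of the
top-k variables by highest off-diagonal |r|; rectangular
feature-versus-clinical-chemistry maps cluster each axis within its own
block.

## Consensus feature selection

Three ranker families — the univariate screen statistic, random-forest
impurity importance, and PLS-DA VIP scores (latent-variable count chosen
once per problem from 2–5 by 3-fold CV) — are each fitted on B = 100
stratified bootstrap resamples (class counts preserved, so no class can
vanish). Each fit emits a full ranking; the 3 × B lists are aggregated by
Borda count: a list of m features awards m − rank points at each rank,
summed over lists, with ties broken by mean rank then feature id and
recorded. A single master seed spawns independent streams per ranker and
per bootstrap.

Forward selection walks down the consensus list: for each k, a random
forest on the top-k features is scored by the .632+ bootstrap
(out-of-bag evaluation on the unsampled remainder, weighted against
resubstitution by the relative overfitting rate). The plain .632
estimator named in older protocols is bounded below ~0.63 for an
interpolating classifier even on permuted labels; the .632+ correction
restores chance-level scores under the null, which the null-simulation
tests require. The optimum k* is the inflection of the accuracy-versus-k
curve, operationalized prospectively: the smallest k from which the mean
gain per feature over the next 5 features of the smoothed (window-5)
curve stays below 0.25 percentage points, capped at k_max. The forward
-looking form keeps transient plateaus in a still-rising curve from
stopping the selection prematurely.

The `ConsensusSelector` estimator wraps the protocol behind the sklearn
fit/transform contract (`support_`, `selected_features_`, `curve_`), so
it composes with pipelines and model selection.

## Sample-size study

For each size n on the 50–650 (step 50) grid, B stratified bootstrap
sample sets of size n are drawn; a classifier (random forest, or RBF-SVM
whose cost is fixed once by CV at the largest size to avoid per-size
tuning confounds) is trained on each set and scored on the unsampled
remainder; the median accuracy and percentile 95 % CI are reported per
size. Ranking consistency at size n is the Spearman correlation between
the Borda-aggregated full ranking on an n-sized stratified subsample and
the full-data ranking; at n equal to the population it is exactly 1, and
on pure-noise data it decays toward the sample-overlap fraction, not to
exactly zero.

The packaged analyses run these studies at reduced scale — 150–500
features, 40–100 resamples — which preserves every qualitative property
(rising medians, narrowing CIs, ranking convergence) at desk-scale cost.
Because percentile CI widths from a finite bootstrap are noisy, the
narrowing-CI property is checked as a strong monotone trend (Spearman
ρ(size, width) ≤ −0.6 with terminal width below initial), not as strict
elementwise monotonicity, which even the underlying estimator does not
satisfy realization-by-realization.

## Numerical conventions

* RSD = 100 · sample SD (n−1) / mean; requires ≥ 2 observations and a
  non-zero mean.
* Ratio-filter boundary: strictly < 1.5 removed; exactly 1.5 retained.
* Presence boundary: ≥ 80 % retained.
* Missingness cap: > 20 % missing is an error at imputation time (such
  features belong to the filters, not the imputer).
* All stochastic stages accept either an integer seed or a Generator;
  identical seeds give bit-identical outputs. Seeds handed to sklearn are
  drawn below 2^31.
* Ranking ties are broken by stable argsort on column order (rankers) or
  mean rank then id (Borda); both are recorded or deterministic.

## Known limitations

* Feature matching across batches is tolerance-based only; adduct and
  isotope grouping, and any spectral identification, are out of scope
  (annotation fields are passed through untouched).
* The GC per-batch QC arithmetic of mixed conditioning/interleaved
  layouts varies between laboratories; conditioning counts and the QC
  interval are exposed as parameters rather than hard-coded.
* Within-run drift components faster than the QC cadence are
  uncorrectable in principle; the corrector does not attempt to model
  them.
* The two-way ANOVA reports Type II tests; with strong interactions,
  main-effect interpretation requires the usual caution.
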