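# metabodrift

Simulation, drift correction, batch integration, quality filtering and
consensus feature selection for large multi-batch chromatography–mass
spectrometry metabolomics studies.

Untargeted serum metabolomics campaigns spanning hundreds to thousands of
subjects must be acquired in many analytical batches over months.
Instrument sensitivity attenuates non-linearly with injection order within
a run and jumps between batches, so raw peak areas confound biology with
acquisition order. The standard countermeasure is periodic injection of a
single pooled quality-control (QC) sample — biologically identical every
time, hence carrying only technical variance — and **QC-RLSC**
(quality-control–based robust LOESS signal correction): for each
metabolite feature and each run, fit a robust locally weighted regression
through the QC peak areas versus injection order,

&nbsp;&nbsp;&nbsp;&nbsp;*ĉ(t) = loess{(tᵢ, QCᵢ)}*, interpolated by cubic
spline to every injection position *t*,

divide the run's areas by *ĉ(t)*, concatenate batches on the normalized
scale, and un-normalize by the feature's median QC peak area across
batches. Features are then screened by QC relative standard deviation
(RSD = 100·SD/mean; tolerance 20 % UPLC–MS, 30 % GC–MS), an 80 %
presence rule, and the information filter (inter-subject RSD / QC RSD
< 1.5 removed). Downstream, the package provides mean imputation,
autoscaling, Mann–Whitney/Kruskal–Wallis screens, Type II two-way ANOVA
with Tukey HSD, correlation heatmap clustering, bootstrap **consensus
feature selection** (univariate + random forest + PLS-DA VIP rankings
over 100 stratified bootstrap resamples, aggregated by Borda count,
optimized by forward-selection remodeling), and an empirical
**sample-size study** (accuracy and ranking consistency versus subsample
size, 50–650 in steps of 50).

Everything is testable without downloads: the `simulate` module generates
multi-batch raw studies with known ground truth (drift curves, batch
steps, planted covariate effects, detection-limit missingness) and a
cohort generator calibrated to a published healthy-adult reference
population (median age 48.0 y, BMI 25.63 kg/m², SBP 125 mmHg, …).

The package targets analytical chemists and biostatisticians building or
validating QC-based correction pipelines, and methodologists who need a
ground-truthed sandbox for feature-selection and power studies.

## Worked example

```python
import metabodrift as md
from metabodrift.simulate import DriftModel, MissingnessParams

# 3 batches x 120 subjects, 200 features, drifting instrument
design = md.build_study_design("UPLC_pos", n_batches=3, subjects_per_batch=120)
cohort = md.generate_cohort(360, seed=1)
features = md.make_feature_catalogue(200, "UPLC_pos", seed=2)
drift = DriftModel(attenuation=(0.2, 0.4), batch_step_sigma=0.3)
batches, truth = md.simulate_study(design, cohort, features, drift,
                                   (), MissingnessParams(), seed=3)

# QC-RLSC correction and batch integration
corrected = [md.correct_batch(b, md.fit_batch_curves(b)[0]) for b in batches]
integrated = md.integrate_study(corrected)

from metabodrift.filters import feature_metrics
import pandas as pd
from metabodrift.correction import compute_rsd
raw_rsd = pd.concat([b.qc_values() for b in batches]).apply(compute_rsd)
print(f"median QC RSD raw:       {raw_rsd.median():5.1f} %")
print(f"median QC RSD corrected: {feature_metrics(integrated)['qc_rsd'].median():5.1f} %")
```

```
median QC RSD raw:        27.5 %
median QC RSD corrected:   4.2 %
```

The pooled-QC scatter — pure technical + drift variance — drops from
~28 % to ~4 %, i.e. to roughly the injected 5 % technical CV: the
injection-order and between-batch structure has been removed while
subject biology (held out of the QC sample by construction) is untouched.

Feature selection on an analysis-ready matrix composes with sklearn:

```python
from metabodrift import ConsensusSelector
from metabodrift.preprocess import autoscale, impute_missing
from metabodrift.simulate import make_classification_study

X, y, informative = make_classification_study(
    n_subjects=200, n_features=500, n_informative=20, effect_size=1.0, seed=4)
sel = ConsensusSelector(B=100, k_max=40, random_state=5).fit(autoscale(X), y)
print(f"k* = {sel.curve_.k_star}, "
      f"accuracy at k* = {sel.curve_.accuracy_at_k_star:.3f}")
print(f"true informatives in top 20: "
      f"{len(set(sel.ranking_.order[:20]) & set(informative))}/20")
```

```
k* = 15, accuracy at k* = 0.974
true informatives in top 20: 20/20
```

A command-line front end wraps the same pipeline
(`metabodrift simulate|correct|qa|stats|select|samplesize|all --config
cfg.yaml --seed 7 --out-dir out/`), writing TSV artifacts, a selection
manifest and a JSON run report.

## Layout

```
src/metabodrift/
  cohort.py       quantile-calibrated synthetic cohorts
  design.py       run / batch / study layouts
  simulate.py     raw-study generator with ground truth
  correction.py   QC-RLSC curve fitting and batch correction
  integrate.py    cross-batch feature matching and un-normalization
  filters.py      QC-RSD, presence and information filters
  preprocess.py   MeanImputer, Autoscaler (sklearn transformers)
  stats.py        screens, two-way ANOVA, Tukey HSD, correlation maps
  consensus.py    bootstrap rankings, Borda count, ConsensusSelector
  samplesize.py   learning curves and ranking consistency
  io.py           TSV dialects with provenance headers
  pipeline.py     config-driven orchestration
  cli.py          click front end
docs/methods.md   models, defaults, numerical conventions
```
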