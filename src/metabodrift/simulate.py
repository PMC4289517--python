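"""Simulation of raw multi-batch peak-area studies with known ground truth.

The generator emulates, at the deconvolved peak-area level, the phenomena a
long chromatography-MS campaign exhibits: smooth multiplicative
injection-order attenuation within a run, step changes in sensitivity
between batches, technical noise on every injection, biological variation
between subjects, planted covariate effects, and detection-limit dropout.

The observed area for injection *i* of feature *f* factorizes as

    raw[i, f] = truth[i, f] * drift[i, f] * noise[i, f]

where ``truth`` is the pooled-QC composition for QC injections (zero
biological variance by construction) or the subject's biological abundance,
``drift`` bundles the batch step and the within-run attenuation curve
``exp(-lambda * (pos - 1)) * (1 + a * sin(2 pi pos / P))``, and ``noise``
is i.i.d. log-normal technical error. The full decomposition is returned
as ground truth, so the emitted study can be reconstructed from it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import ValidationError, check_rng
from .design import BatchDesign, ROLE_CONDITIONING, ROLE_SUBJECT
from .groups import hypothesis_labels
from .matrix import PeakMatrix


def make_feature_catalogue(
    n_features: int, platform: str = "UPLC_pos", seed=None
) -> pd.DataFrame:
    """Feature metadata: id, platform, m/z + RT (UPLC) or retention index (GC),
    a log-normal baseline abundance, and passthrough annotation fields."""
    rng = check_rng(seed)
    prefix = {"GCMS": "G", "UPLC_pos": "P", "UPLC_neg": "N"}.get(platform, "F")
    ids = [f"{prefix}{i + 1:04d}" for i in range(n_features)]
    cat = pd.DataFrame(index=pd.Index(ids, name="feature_id"))
    cat["platform"] = platform
    # baselines span ~3 orders of magnitude around 1e5 counts
    cat["baseline"] = np.exp(rng.normal(np.log(1e5), 1.2, size=n_features))
    if platform == "GCMS":
        cat["retention_index"] = np.round(rng.uniform(800, 3000, size=n_features), 1)
        cat["mz"] = np.nan
        cat["rt"] = np.nan
    else:
        cat["mz"] = np.round(rng.uniform(80, 1200, size=n_features), 4)
        cat["rt"] = np.round(rng.uniform(0.5, 21.5, size=n_features), 3)
        cat["retention_index"] = np.nan
    cat["annotation"] = ""
    cat["msi_level"] = 4
    return cat


@dataclass(frozen=True)
class DriftModel:
    """Parameters of the multiplicative instrument-drift process.

    attenuation : (lo, hi)
        Per-feature terminal signal loss over a run is drawn uniformly from
        this range; 0.4 means the last injection retains 60 % of the first.
    sin_amplitude : (lo, hi)
        Amplitude range of the low-frequency sinusoidal component.
    sin_period : (lo, hi)
        Sinusoid period range as multiples of the run length.
    batch_step_sigma : float
        Log-SD of the per-feature, per-batch sensitivity step factor.
    technical_cv : float
        Coefficient of variation of injection-to-injection technical noise
        (the only variance a pooled QC shows).
    biological_cv : float
        Between-subject coefficient of variation of true abundances.
    """

    attenuation: tuple[float, float] = (0.0, 0.4)
    sin_amplitude: tuple[float, float] = (0.0, 0.1)
    sin_period: tuple[float, float] = (0.5, 2.0)
    batch_step_sigma: float = 0.1
    technical_cv: float = 0.05
    biological_cv: float = 0.45

    def __post_init__(self):
        if self.technical_cv < 0 or self.biological_cv < 0:
            raise ValidationError("CVs must be >= 0")
        if not 0 <= self.attenuation[0] <= self.attenuation[1] < 1:
            raise ValidationError("attenuation range must lie in [0, 1)")
        if self.sin_amplitude[1] >= 1:
            raise ValidationError("sinusoid amplitude must stay below 1")


@dataclass(frozen=True)
class EffectSpec:
    """A planted covariate effect.

    Subjects in ``low_level`` of ``factor`` are shifted by -effect_size/2
    and those in ``high_level`` by +effect_size/2, in units of the
    biological log-SD, on every feature in ``features``. Other levels (and
    excluded subjects) are unshifted.
    """

    factor: str
    features: tuple
    effect_size: float
    low_level: str
    high_level: str

    def __post_init__(self):
        if not np.isfinite(self.effect_size):
            raise ValidationError("effect size must be finite")


@dataclass(frozen=True)
class MissingnessParams:
    """Detection-limit (MNAR) left-censoring plus a small MCAR component.

    Values below the per-feature ``mnar_quantile`` of raw areas become
    missing; every remaining cell is additionally dropped with probability
    ``mcar_rate``.
    """

    mnar_quantile: float = 0.02
    mcar_rate: float = 0.01


@dataclass
class GroundTruth:
    """Exact decomposition of the emitted raw study.

    raw = truth * drift * noise, masked by ``missing_mask``. All tables are
    indexed by the global sample_id in injection order.
    """

    samples: pd.DataFrame
    truth: pd.DataFrame
    drift: pd.DataFrame
    noise: pd.DataFrame
    missing_mask: pd.DataFrame
    informative: dict = field(default_factory=dict)
    effects: tuple = ()

    def reconstruct_raw(self) -> pd.DataFrame:
        raw = self.truth * self.drift * self.noise
        return raw.mask(self.missing_mask)

    def subject_truth(self) -> pd.DataFrame:
        mask = (self.samples["role"] == ROLE_SUBJECT).to_numpy()
        out = self.truth.loc[mask].copy()
        out.index = self.samples.loc[mask, "subject_id"].to_numpy()
        return out


def _cv_to_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv**2)))


def make_classification_study(
    n_subjects: int,
    n_features: int,
    n_informative: int,
    effect_size: float,
    factor: str = "gender",
    drift: DriftModel = DriftModel(),
    platform: str = "UPLC_pos",
    seed=None,
):
    """Subject-level matrix with a planted group effect; no drift applied.

    Convenience front-end for selection and sample-size studies: draws a
    cohort, plants ``effect_size`` (biological-SD units) on the first
    ``n_informative`` features for ``factor``, and returns
    ``(values, labels, informative_ids)`` where values are biological
    abundances times technical noise.
    """
    from .cohort import generate_cohort  # local import avoids a cycle

    rng = check_rng(seed)
    cohort = generate_cohort(n_subjects, seed=rng, include_clinical=False)
    catalogue = make_feature_catalogue(n_features, platform, seed=rng)
    labels = hypothesis_labels(cohort, factor)
    levels = sorted(set(labels.dropna()))
    informative = tuple(catalogue.index[:n_informative])
    sigma_bio = _cv_to_sigma(drift.biological_cv)
    sigma_tech = _cv_to_sigma(drift.technical_cv)
    baseline = catalogue["baseline"].to_numpy(dtype=float)

    log_vals = rng.normal(0.0, sigma_bio, size=(n_subjects, n_features))
    shift = effect_size * sigma_bio / 2.0
    cols = np.arange(n_informative)
    lo = (labels == levels[0]).to_numpy()
    hi = (labels == levels[-1]).to_numpy()
    log_vals[np.ix_(lo, cols)] -= shift
    log_vals[np.ix_(hi, cols)] += shift
    values = baseline[None, :] * np.exp(
        log_vals + rng.normal(0.0, sigma_tech, size=log_vals.shape)
    )
    frame = pd.DataFrame(values, index=cohort.index, columns=catalogue.index)
    keep = labels.notna().to_numpy()
    return frame.loc[keep], labels[keep], informative


def _drift_curve(
    positions: np.ndarray, retention: np.ndarray, amp: np.ndarray, period: np.ndarray
) -> np.ndarray:
    """Per-feature multiplicative drift at 1-based positions (n_pos x n_feat)."""
    L = positions.max()
    pos = positions[:, None].astype(float)
    lam = np.where(L > 1, -np.log(retention) / max(L - 1, 1), 0.0)[None, :]
    base = np.exp(-lam * (pos - 1.0))
    wig = 1.0 + amp[None, :] * np.sin(2 * np.pi * pos / period[None, :])
    curve = base * wig
    if (curve <= 0).any():
        raise ValidationError("drift factor must stay strictly positive")
    return curve


def simulate_study(
    study_design: list[BatchDesign],
    cohort: pd.DataFrame,
    feature_catalogue: pd.DataFrame,
    drift: DriftModel = DriftModel(),
    effects: tuple[EffectSpec, ...] = (),
    missingness: MissingnessParams | None = MissingnessParams(),
    seed=None,
) -> tuple[list[PeakMatrix], GroundTruth]:
    """Simulate a multi-batch study; returns raw batches plus ground truth.

    The cohort must have exactly as many subjects as the design has subject
    slots; subjects are assigned to slots in cohort order (the cohort is
    itself randomized, mirroring near-random batch composition).
    """
    n_slots = sum(b.n_subjects for b in study_design)
    if n_slots != len(cohort):
        raise ValidationError(
            f"design has {n_slots} subject slots but cohort has {len(cohort)}"
        )
    rng = check_rng(seed)
    features = feature_catalogue.index.to_numpy()
    n_feat = len(features)
    baseline = feature_catalogue["baseline"].to_numpy(dtype=float)
    sigma_bio = _cv_to_sigma(drift.biological_cv)
    sigma_tech = _cv_to_sigma(drift.technical_cv)

    unknown = [
        f
        for spec in effects
        for f in spec.features
        if f not in feature_catalogue.index
    ]
    if unknown:
        raise ValidationError(f"effect features not in catalogue: {unknown[:5]}")

    # per-subject biological log-offsets: base variation + planted effects
    subj_log = rng.normal(0.0, sigma_bio, size=(len(cohort), n_feat))
    informative: dict[str, list] = {}
    feat_pos = {f: j for j, f in enumerate(features)}
    for spec in effects:
        labels = hypothesis_labels(cohort, spec.factor)
        cols = np.array([feat_pos[f] for f in spec.features])
        shift = spec.effect_size * sigma_bio / 2.0
        lo = (labels == spec.low_level).to_numpy()
        hi = (labels == spec.high_level).to_numpy()
        subj_log[np.ix_(lo, cols)] -= shift
        subj_log[np.ix_(hi, cols)] += shift
        informative.setdefault(spec.factor, []).extend(spec.features)
    subject_values = baseline[None, :] * np.exp(subj_log)

    raw_batches: list[PeakMatrix] = []
    gt_samples, gt_truth, gt_drift, gt_noise, gt_mask = [], [], [], [], []
    subj_cursor = 0
    subject_ids = cohort.index.to_numpy()

    for batch in study_design:
        b_samples, b_truth, b_drift = [], [], []
        for r_idx, run in enumerate(batch.runs):
            run_id = f"{batch.batch_id}_R{r_idx + 1}"
            positions = np.array([p for p, _ in run.injection_sequence])
            roles = [r for _, r in run.injection_sequence]

            retention = 1.0 - rng.uniform(*drift.attenuation, size=n_feat)
            amp = rng.uniform(*drift.sin_amplitude, size=n_feat)
            L = len(positions)
            period = rng.uniform(*drift.sin_period, size=n_feat) * L
            step = np.exp(rng.normal(0.0, drift.batch_step_sigma, size=n_feat))
            curve = _drift_curve(positions, retention, amp, period) * step[None, :]

            truth_rows = np.empty((L, n_feat))
            ids, subj_col = [], []
            for i, (pos, role) in enumerate(zip(positions, roles)):
                if role == ROLE_SUBJECT:
                    sid = subject_ids[subj_cursor]
                    truth_rows[i] = subject_values[subj_cursor]
                    subj_cursor += 1
                    ids.append(str(sid))
                    subj_col.append(str(sid))
                else:
                    tag = "CQC" if role == ROLE_CONDITIONING else "QC"
                    truth_rows[i] = baseline
                    ids.append(f"{run_id}_{tag}{pos:03d}")
                    subj_col.append("")
            srun = pd.DataFrame(
                {
                    "sample_id": ids,
                    "batch_id": batch.batch_id,
                    "run_id": run_id,
                    "injection_order": positions,
                    "role": roles,
                    "subject_id": subj_col,
                }
            )
            b_samples.append(srun)
            b_truth.append(truth_rows)
            b_drift.append(curve)

        samples = pd.concat(b_samples, ignore_index=True)
        truth = np.vstack(b_truth)
        drift_mat = np.vstack(b_drift)
        noise = np.exp(rng.normal(0.0, sigma_tech, size=truth.shape))
        raw = truth * drift_mat * noise

        raw_df = pd.DataFrame(raw, columns=features)
        if missingness is not None:
            thresh = np.quantile(raw, missingness.mnar_quantile, axis=0)
            mask = raw < thresh[None, :]
            mask |= rng.uniform(size=raw.shape) < missingness.mcar_rate
        else:
            mask = np.zeros(raw.shape, dtype=bool)
        raw_df = raw_df.mask(mask)

        raw_batches.append(
            PeakMatrix(
                samples=samples.drop(columns="subject_id"),
                values=raw_df,
                features=feature_catalogue.copy(),
            )
        )
        sid_index = pd.Index(samples["sample_id"], name="sample_id")
        gt_samples.append(samples.set_index(sid_index))
        gt_truth.append(pd.DataFrame(truth, index=sid_index, columns=features))
        gt_drift.append(pd.DataFrame(drift_mat, index=sid_index, columns=features))
        gt_noise.append(pd.DataFrame(noise, index=sid_index, columns=features))
        gt_mask.append(pd.DataFrame(mask, index=sid_index, columns=features))

    ground_truth = GroundTruth(
        samples=pd.concat(gt_samples),
        truth=pd.concat(gt_truth),
        drift=pd.concat(gt_drift),
        noise=pd.concat(gt_noise),
        missing_mask=pd.concat(gt_mask),
        informative={k: sorted(set(v)) for k, v in informative.items()},
        effects=tuple(effects),
    )
    return raw_batches, ground_truth
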