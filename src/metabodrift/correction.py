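"""QC-based robust LOESS signal correction (QC-RLSC) within analytical runs.

For each feature and run, a robust locally-weighted regression (tricube
weights, local linear fit) is passed through the pooled-QC peak areas
versus injection order; a cubic spline interpolates the fitted values to
every injection position, held constant beyond the terminal QCs; the run's
data for that feature are then divided by this correction curve, removing
injection-order attenuation while the robustification avoids chasing
random measurement error. The LOESS span is chosen per feature by
leave-one-out cross-validation over a small grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._utils import ValidationError
from .design import ROLE_QC
from .matrix import PeakMatrix

DEFAULT_SPAN_GRID = (0.3, 0.5, 0.75, 1.0)


def compute_rsd(values) -> float:
    """Relative standard deviation, percent: 100 * sample SD / mean.

    Missing values are ignored; requires at least two observations and a
    non-zero mean.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise ValidationError(f"RSD needs >= 2 non-missing values, got {x.size}")
    mean = x.mean()
    if mean == 0:
        raise ValidationError("RSD undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / mean)


class UncorrectableFeature(ValidationError):
    """Too few usable QC points to fit a correction curve."""


@dataclass
class LoessParams:
    span_grid: tuple = DEFAULT_SPAN_GRID
    robust_iters: int = 2
    min_qc_points: int = 4


@dataclass
class CorrectionCurve:
    """Positive per-feature correction factor at every position of one run."""

    feature_id: str
    run_id: str
    positions: np.ndarray
    factors: np.ndarray
    span: float
    fallback: bool = False  # constant median fallback due to non-positive fit
    qc_positions: np.ndarray = field(default=None, repr=False)
    qc_fitted: np.ndarray = field(default=None, repr=False)

    def factor_at(self, positions) -> np.ndarray:
        pos = np.asarray(positions)
        lookup = {int(p): f for p, f in zip(self.positions, self.factors)}
        try:
            return np.array([lookup[int(p)] for p in np.atleast_1d(pos)])
        except KeyError as exc:
            raise ValidationError(f"position {exc} not covered by curve") from exc


def _lowess_fit(x, y, frac, it):
    # guard: a local window of fewer than 3 points makes the local linear
    # fit degenerate. Fitted values are requested at the data points
    # themselves (the xvals fast path misbehaves under robust iterations).
    frac = max(frac, min(1.0, 3.0 / len(x)))
    out = lowess(y, x, frac=frac, it=it, return_sorted=False)
    return np.asarray(out, dtype=float)


def _loo_error(x, y, frac) -> float:
    n = len(x)
    err = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        pred = lowess(y[keep], x[keep], frac=max(frac, min(1.0, 3.0 / (n - 1))),
                      it=0, xvals=np.array([x[i]]))
        err += float((y[i] - pred[0]) ** 2)
    return err


def fit_correction_curve(
    qc_points,
    run_positions,
    loess_params: LoessParams | None = None,
    feature_id: str = "",
    run_id: str = "",
) -> CorrectionCurve:
    """Fit the QC-RLSC correction curve for one feature in one run.

    Parameters
    ----------
    qc_points : sequence of (injection_order, area)
        Pooled-QC observations (conditioning injections must not be
        included). NaN areas are dropped.
    run_positions : array-like
        Every injection position of the run at which the curve is needed.

    Raises
    ------
    UncorrectableFeature
        Fewer than ``min_qc_points`` usable QC observations.
    """
    params = loess_params or LoessParams()
    pts = np.asarray(list(qc_points), dtype=float)
    if pts.size:
        pts = pts[~np.isnan(pts[:, 1])]
    if len(pts) < params.min_qc_points:
        raise UncorrectableFeature(
            f"{len(pts)} QC points < min {params.min_qc_points} "
            f"(feature {feature_id!r}, run {run_id!r})"
        )
    order = np.argsort(pts[:, 0])
    x, y = pts[order, 0], pts[order, 1]
    run_positions = np.asarray(run_positions)

    scale = max(np.abs(y).max(), 1e-300)
    if np.ptp(y) <= 1e-12 * scale:
        # constant QC signal: the curve is that constant everywhere
        const = float(y.mean())
        factors = np.full(run_positions.shape, const, dtype=float)
        return _finalize(feature_id, run_id, run_positions, factors, 1.0, x, y, y)

    best_span = min(params.span_grid, key=lambda f: _loo_error(x, y, f))
    fitted = _lowess_fit(x, y, best_span, it=0)
    resid = y - fitted
    if params.robust_iters and np.median(np.abs(resid)) > 1e-12 * scale:
        fitted = _lowess_fit(x, y, best_span, it=params.robust_iters)

    spline = CubicSpline(x, fitted, bc_type="natural")
    factors = np.empty(run_positions.shape, dtype=float)
    inside = (run_positions >= x[0]) & (run_positions <= x[-1])
    factors[inside] = spline(run_positions[inside])
    factors[run_positions < x[0]] = fitted[0]
    factors[run_positions > x[-1]] = fitted[-1]
    return _finalize(feature_id, run_id, run_positions, factors, best_span, x, y, fitted)


def _finalize(feature_id, run_id, positions, factors, span, qc_x, qc_y, qc_fit):
    if (factors <= 0).any() or not np.isfinite(factors).all():
        # non-positive fit: fall back to the global median of QC areas
        factors = np.full(positions.shape, float(np.median(qc_y)))
        return CorrectionCurve(
            feature_id, run_id, positions, factors, span,
            fallback=True, qc_positions=qc_x, qc_fitted=qc_fit,
        )
    return CorrectionCurve(
        feature_id, run_id, positions, factors, span,
        qc_positions=qc_x, qc_fitted=qc_fit,
    )


def fit_batch_curves(
    batch: PeakMatrix, loess_params: LoessParams | None = None
) -> tuple[dict, list]:
    """Fit curves for every (feature, run) of a batch.

    Only role == QC injections enter the fit (conditioning QCs condition
    the column, not the statistics). Returns ``(curves, uncorrectable)``
    where curves maps (feature_id, run_id) -> CorrectionCurve and
    uncorrectable lists (feature_id, run_id, reason).
    """
    curves: dict = {}
    uncorrectable: list = []
    for run_id, idx in batch.samples.groupby("run_id").groups.items():
        sub = batch.samples.loc[idx]
        run_positions = sub["injection_order"].to_numpy()
        qc_rows = idx[(sub["role"] == ROLE_QC).to_numpy()]
        qc_pos = batch.samples.loc[qc_rows, "injection_order"].to_numpy()
        for fid in batch.feature_ids:
            areas = batch.values.loc[qc_rows, fid].to_numpy(dtype=float)
            try:
                curves[(fid, run_id)] = fit_correction_curve(
                    list(zip(qc_pos, areas)),
                    run_positions,
                    loess_params,
                    feature_id=fid,
                    run_id=run_id,
                )
            except UncorrectableFeature as exc:
                uncorrectable.append((fid, run_id, str(exc)))
    return curves, uncorrectable


def correct_batch(batch: PeakMatrix, curves: dict) -> PeakMatrix:
    """Divide every cell by its correction-curve factor (normalized scale).

    Missing cells stay missing. Features with no curve for a run they
    appear in are set missing for that run (the NaN rule). Conditioning
    injections are corrected too, for audit, though they never entered the
    fit. The per-batch median raw QC area of each feature is recorded in
    ``features['qc_median_raw']`` for later un-normalization.
    """
    out = batch.copy()
    qc_mask = out.rows(ROLE_QC)
    qc_median = out.values.loc[qc_mask].median(axis=0, skipna=True)
    for run_id, idx in out.samples.groupby("run_id").groups.items():
        positions = out.samples.loc[idx, "injection_order"].to_numpy()
        for fid in out.feature_ids:
            curve = curves.get((fid, run_id))
            if curve is None:
                out.values.loc[idx, fid] = np.nan
                continue
            out.values.loc[idx, fid] = (
                out.values.loc[idx, fid].to_numpy(dtype=float)
                / curve.factor_at(positions)
            )
    out.features = out.features.copy()
    out.features["qc_median_raw"] = qc_median
    return out
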