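"""Imputation and autoscaling ahead of statistical analysis.

Missing cells (at most 20 % per feature after the upstream filters) are
replaced by the feature mean over observed subjects; every feature is then
autoscaled — mean-centred and divided by its sample standard deviation —
so all features contribute on an equal variance scale.

Both steps are sklearn-compatible transformers so they drop into
``sklearn.pipeline.Pipeline``; the module-level functions are thin
wrappers for DataFrame-in/DataFrame-out use.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from ._utils import ValidationError

MAX_MISSING_FRACTION = 0.20


def _as_2d(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), X.columns, X.index
    return check_array(X, ensure_all_finite="allow-nan", dtype=float), None, None


class MeanImputer(TransformerMixin, BaseEstimator):
    """Feature-mean imputation with a hard missingness cap.

    Parameters
    ----------
    max_missing : float, default 0.20
        Features with a higher missing fraction raise at fit time: they
        should have been removed by the presence filter, not imputed.
    """

    def __init__(self, max_missing: float = MAX_MISSING_FRACTION):
        self.max_missing = max_missing

    def fit(self, X, y=None):
        arr, cols, _ = _as_2d(X)
        frac = np.isnan(arr).mean(axis=0)
        if (frac == 1.0).any():
            bad = np.flatnonzero(frac == 1.0)
            raise ValidationError(f"features entirely missing: columns {bad[:5]}")
        if (frac > self.max_missing).any():
            bad = np.flatnonzero(frac > self.max_missing)
            names = list(cols[bad][:5]) if cols is not None else list(bad[:5])
            raise ValidationError(
                f"{bad.size} features exceed {self.max_missing:.0%} missing "
                f"(e.g. {names}); apply the presence/QA filters first"
            )
        self.statistics_ = np.nanmean(arr, axis=0)
        self.n_features_in_ = arr.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        arr, cols, idx = _as_2d(X)
        out = np.where(np.isnan(arr), self.statistics_[None, :], arr)
        if cols is not None:
            return pd.DataFrame(out, index=idx, columns=cols)
        return out


class Autoscaler(TransformerMixin, BaseEstimator):
    """Per-feature mean-centring and unit (sample) variance scaling."""

    def fit(self, X, y=None):
        arr, cols, _ = _as_2d(X)
        if np.isnan(arr).any():
            raise ValidationError("autoscaling requires a complete matrix; impute first")
        sd = arr.std(axis=0, ddof=1)
        if (sd == 0).any() or np.isnan(sd).any():
            bad = np.flatnonzero((sd == 0) | np.isnan(sd))
            names = list(cols[bad][:5]) if cols is not None else list(bad[:5])
            raise ValidationError(f"zero-variance features: {names}")
        self.mean_ = arr.mean(axis=0)
        self.scale_ = sd
        self.n_features_in_ = arr.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        arr, cols, idx = _as_2d(X)
        out = (arr - self.mean_[None, :]) / self.scale_[None, :]
        if cols is not None:
            return pd.DataFrame(out, index=idx, columns=cols)
        return out


def impute_missing(matrix: pd.DataFrame, max_missing: float = MAX_MISSING_FRACTION):
    """Replace each missing cell by its feature's mean over observed subjects."""
    return MeanImputer(max_missing=max_missing).fit_transform(matrix)


def autoscale(matrix: pd.DataFrame):
    """Mean-centre and scale every feature to unit sample variance."""
    return Autoscaler().fit_transform(matrix)
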