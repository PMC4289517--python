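"""Tabular containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import ValidationError
from .design import ROLE_CONDITIONING, ROLE_QC, ROLE_SUBJECT

SAMPLE_COLUMNS = ("sample_id", "batch_id", "run_id", "injection_order", "role")
ROLES = (ROLE_CONDITIONING, ROLE_QC, ROLE_SUBJECT)


@dataclass
class PeakMatrix:
    """Injections x features peak-area table with injection metadata.

    ``samples`` holds one row per injection (sample_id, batch_id, run_id,
    injection_order, role); ``values`` is positionally aligned with it and
    holds one column per feature (NaN = missing); ``features`` is indexed by
    feature_id and carries platform, m/z + retention time (UPLC) or
    retention index (GC) and passthrough annotation metadata.
    """

    samples: pd.DataFrame
    values: pd.DataFrame
    features: pd.DataFrame = field(default=None)

    def __post_init__(self):
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValidationError(f"samples table missing columns: {missing}")
        if len(self.samples) != len(self.values):
            raise ValidationError("samples and values row counts differ")
        bad_roles = set(self.samples["role"]) - set(ROLES)
        if bad_roles:
            raise ValidationError(f"unknown roles: {sorted(bad_roles)}")
        for run_id, grp in self.samples.groupby("run_id"):
            if grp["injection_order"].duplicated().any():
                raise ValidationError(f"duplicate injection_order in run {run_id}")
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy(dtype=float) < 0).any():
                raise ValidationError("negative peak areas")
        if self.features is None:
            self.features = pd.DataFrame(index=self.values.columns)
        self.samples = self.samples.reset_index(drop=True)
        self.values = self.values.reset_index(drop=True)

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.columns

    def rows(self, role: str) -> np.ndarray:
        return (self.samples["role"] == role).to_numpy()

    def subject_values(self) -> pd.DataFrame:
        out = self.values.loc[self.rows(ROLE_SUBJECT)].copy()
        out.index = self.samples.loc[self.rows(ROLE_SUBJECT), "sample_id"]
        return out

    def qc_values(self, include_conditioning: bool = False) -> pd.DataFrame:
        mask = self.rows(ROLE_QC)
        if include_conditioning:
            mask = mask | self.rows(ROLE_CONDITIONING)
        out = self.values.loc[mask].copy()
        out.index = self.samples.loc[mask, "sample_id"]
        return out

    def copy(self) -> "PeakMatrix":
        return PeakMatrix(
            self.samples.copy(), self.values.copy(), self.features.copy()
        )


@dataclass
class IntegratedMatrix:
    """Subjects x features matrix on the un-normalized intensity scale.

    QC injections are excluded from ``values`` but retained (same scale) in
    ``qc_values`` for audit; ``features`` records per-feature provenance:
    contributing batches, the median QC peak area used for un-normalization,
    and the missing fraction over subjects.
    """

    values: pd.DataFrame  # index: subject sample_id
    qc_values: pd.DataFrame  # index: QC sample_id
    features: pd.DataFrame  # index: feature_id

    def __post_init__(self):
        if not self.values.columns.equals(self.qc_values.columns):
            raise ValidationError("subject and QC tables must share feature columns")

    @property
    def missing_fraction(self) -> pd.Series:
        return self.values.isna().mean()

    def select_features(self, keep) -> "IntegratedMatrix":
        keep = list(keep)
        return IntegratedMatrix(
            self.values[keep].copy(),
            self.qc_values[keep].copy(),
            self.features.loc[keep].copy(),
        )
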