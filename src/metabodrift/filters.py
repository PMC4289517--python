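"""Quality-assurance and information filters on the integrated matrix.

Filter order follows the pipeline narrative: (1) post-correction QC RSD
against the platform tolerance (20 % for UPLC-MS, 30 % for GC-MS);
(2) presence in at least 80 % of subject samples; (3) the information
filter, removing features whose inter-subject RSD / QC RSD ratio is
strictly below 1.5 — such features carry no usable biological signal.
Every removal carries exactly one primary reason code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correction import compute_rsd
from .matrix import IntegratedMatrix

logger = logging.getLogger(__name__)

RSD_TOLERANCE = {"GCMS": 30.0, "UPLC_pos": 20.0, "UPLC_neg": 20.0}
PRESENCE_THRESHOLD = 0.80
RATIO_THRESHOLD = 1.5

REASON_QC_RSD = "qc_rsd"
REASON_PRESENCE = "presence"
REASON_RATIO = "rsd_ratio"


def _safe_rsd(values: pd.Series) -> float:
    x = values.to_numpy(dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2 or x.mean() == 0:
        return np.nan
    return compute_rsd(x)


@dataclass
class QAReport:
    """Per-feature QA decisions plus batch-level counts."""

    table: pd.DataFrame  # per feature: metrics, pass/fail, primary reason
    n_in: int = 0
    n_out: int = 0

    def __post_init__(self):
        removed = self.table["reason"].notna().sum()
        if self.n_in - removed != self.n_out:
            raise AssertionError("QA report counts do not sum")


def feature_metrics(matrix: IntegratedMatrix) -> pd.DataFrame:
    """QC RSD, inter-subject RSD, presence fraction and RSD ratio per feature."""
    qc_rsd = matrix.qc_values.apply(_safe_rsd)
    subject_rsd = matrix.values.apply(_safe_rsd)
    presence = 1.0 - matrix.missing_fraction
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(qc_rsd == 0, np.inf, subject_rsd / qc_rsd)
    return pd.DataFrame(
        {
            "qc_rsd": qc_rsd,
            "subject_rsd": subject_rsd,
            "presence": presence,
            "rsd_ratio": pd.Series(ratio, index=qc_rsd.index),
        }
    )


def qa_filter(
    matrix: IntegratedMatrix,
    platform: str | None = None,
    rsd_tolerance: float | None = None,
    presence_threshold: float = PRESENCE_THRESHOLD,
) -> tuple[IntegratedMatrix, QAReport]:
    """Remove features failing the QC-RSD tolerance or the presence rule.

    A feature fails if its post-correction QC RSD exceeds the platform
    tolerance (strictly), or if it is present in fewer than 80 % of
    subject samples (>= 80 % retained). A feature whose QC RSD cannot be
    computed (all-missing QC column) fails the RSD check.
    """
    if rsd_tolerance is None:
        if platform is None:
            platform = str(matrix.features["platform"].iloc[0])
        rsd_tolerance = RSD_TOLERANCE[platform]
    metrics = feature_metrics(matrix)

    reason = pd.Series(pd.NA, index=metrics.index, dtype="object")
    fail_rsd = metrics["qc_rsd"].isna() | (metrics["qc_rsd"] > rsd_tolerance)
    reason[fail_rsd] = REASON_QC_RSD
    fail_presence = metrics["presence"] < presence_threshold
    reason[fail_presence & reason.isna()] = REASON_PRESENCE

    table = metrics.assign(reason=reason, kept=reason.isna())
    keep = table.index[table["kept"]]
    if keep.empty:
        logger.warning("qa_filter removed every feature")
    report = QAReport(table=table, n_in=len(metrics), n_out=len(keep))
    return matrix.select_features(keep), report


def information_filter(
    matrix: IntegratedMatrix,
    threshold: float = RATIO_THRESHOLD,
) -> tuple[IntegratedMatrix, QAReport]:
    """Remove features with inter-subject RSD / QC RSD strictly below 1.5.

    A zero QC RSD gives an infinite ratio: the feature is retained and the
    case logged. A ratio of exactly 1.5 is retained (strict inequality).
    """
    metrics = feature_metrics(matrix)
    n_inf = int(np.isinf(metrics["rsd_ratio"]).sum())
    if n_inf:
        logger.info("%d features with zero QC RSD retained (infinite ratio)", n_inf)
    reason = pd.Series(pd.NA, index=metrics.index, dtype="object")
    reason[metrics["rsd_ratio"] < threshold] = REASON_RATIO
    table = metrics.assign(reason=reason, kept=reason.isna())
    keep = table.index[table["kept"]]
    report = QAReport(table=table, n_in=len(metrics), n_out=len(keep))
    return matrix.select_features(keep), report
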