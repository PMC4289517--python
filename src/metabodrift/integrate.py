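"""Integration of corrected batches into one subjects x features matrix.

Features are matched across batches (m/z ppm + retention-time window for
UPLC, library identity for GC), the normalized values concatenated, and
each merged feature un-normalized by its expected QC peak area — the
median of the per-batch median raw QC areas — restoring an interpretable
intensity scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import ValidationError
from .matrix import IntegratedMatrix, PeakMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchingTolerance:
    mz_ppm: float = 10.0
    rt_window: float = 0.1  # minutes


def _match_features(batches: list[PeakMatrix], tol: MatchingTolerance) -> list[dict]:
    """Map each batch's features onto merged feature ids.

    GC features match by library identity (feature_id); UPLC features match
    a seed when within both the m/z ppm and RT tolerances, nearest m/z
    winning among multiple candidates (logged).
    """
    platform = str(batches[0].features["platform"].iloc[0])
    if platform == "GCMS":
        return [{fid: fid for fid in b.feature_ids} for b in batches]

    seeds: list[tuple[str, float, float]] = []  # (merged_id, mz, rt)
    mappings: list[dict] = []
    for b in batches:
        mapping: dict = {}
        for fid in b.feature_ids:
            mz = float(b.features.at[fid, "mz"])
            rt = float(b.features.at[fid, "rt"])
            cands = [
                (abs(mz - smz), sid)
                for sid, smz, srt in seeds
                if abs(mz - smz) <= tol.mz_ppm * 1e-6 * smz
                and abs(rt - srt) <= tol.rt_window
            ]
            if cands:
                if len(cands) > 1:
                    logger.info(
                        "feature %s matched %d seeds; nearest-m/z rule applied",
                        fid, len(cands),
                    )
                mapping[fid] = min(cands)[1]
            else:
                seeds.append((fid, mz, rt))
                mapping[fid] = fid
        mappings.append(mapping)
    return mappings


def integrate_study(
    corrected_batches: list[PeakMatrix],
    tolerance: MatchingTolerance | None = None,
) -> IntegratedMatrix:
    """Merge corrected batches into one un-normalized subjects x features matrix.

    Batches must share a platform and must have been produced by
    ``correct_batch`` (which records per-batch median raw QC areas).
    Subjects become rows; QC injections (excluding conditioning) are
    carried separately for audit on the same scale. A feature absent from
    a batch yields missing values for that batch's subjects.
    """
    if not corrected_batches:
        raise ValidationError("no batches to integrate")
    platforms = {str(b.features["platform"].iloc[0]) for b in corrected_batches}
    if len(platforms) > 1:
        raise ValidationError(f"batches span platforms {sorted(platforms)}")
    for b in corrected_batches:
        if "qc_median_raw" not in b.features.columns:
            raise ValidationError("batch lacks QC medians; run correct_batch first")

    tol = tolerance or MatchingTolerance()
    mappings = _match_features(corrected_batches, tol)

    merged_ids: list[str] = []
    for mapping in mappings:
        for mid in mapping.values():
            if mid not in merged_ids:
                merged_ids.append(mid)

    subj_parts, qc_parts, meta_rows = [], [], {}
    qc_medians: dict[str, list[float]] = {m: [] for m in merged_ids}
    batch_presence: dict[str, list[str]] = {m: [] for m in merged_ids}
    for b, mapping in zip(corrected_batches, mappings):
        rename = {fid: mapping[fid] for fid in b.feature_ids}
        subj = b.subject_values().rename(columns=rename)
        qc = b.qc_values(include_conditioning=False).rename(columns=rename)
        subj = subj.reindex(columns=merged_ids)
        qc = qc.reindex(columns=merged_ids)
        subj_parts.append(subj)
        qc_parts.append(qc)
        batch_id = str(b.samples["batch_id"].iloc[0])
        for fid in b.feature_ids:
            mid = rename[fid]
            med = float(b.features.at[fid, "qc_median_raw"])
            if np.isfinite(med):
                qc_medians[mid].append(med)
            batch_presence[mid].append(batch_id)
            if mid not in meta_rows:
                meta_rows[mid] = b.features.loc[fid].drop(
                    labels=["qc_median_raw"], errors="ignore"
                )

    values = pd.concat(subj_parts)
    qc_values = pd.concat(qc_parts)
    if values.index.has_duplicates:
        raise ValidationError("duplicate subject sample_id across batches")

    unnorm = pd.Series(
        {m: (np.median(v) if v else np.nan) for m, v in qc_medians.items()}
    )
    values = values.mul(unnorm, axis=1)
    qc_values = qc_values.mul(unnorm, axis=1)

    features = pd.DataFrame(meta_rows).T
    features.index.name = "feature_id"
    features = features.loc[merged_ids]
    features["qc_median"] = unnorm
    features["n_batches"] = pd.Series(
        {m: len(set(v)) for m, v in batch_presence.items()}
    )
    features["batches"] = pd.Series(
        {m: ",".join(sorted(set(v))) for m, v in batch_presence.items()}
    )
    out = IntegratedMatrix(values=values, qc_values=qc_values, features=features)
    out.features["missing_fraction"] = out.missing_fraction
    return out
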