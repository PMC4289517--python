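"""TSV readers/writers for the pipeline's tabular artifacts.

The canonical peak-table dialect is TSV with header columns sample_id,
batch_id, run_id, injection_order, role, followed by one column per
feature; missing cells are written "NA". Feature metadata travels in a
companion TSV (feature_id, platform, mz, rt / retention_index, annotation,
msi_level). Output files carry '#'-prefixed provenance header lines (tool
version, config hash, seed).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import MISSING, ValidationError
from .cohort import validate_cohort
from .matrix import SAMPLE_COLUMNS, IntegratedMatrix, PeakMatrix

try:  # version for provenance headers
    from importlib.metadata import version as _pkg_version

    __version__ = _pkg_version("metabodrift")
except Exception:  # pragma: no cover
    __version__ = "unknown"


def _provenance_lines(seed=None, config: dict | None = None) -> list[str]:
    lines = [f"# metabodrift {__version__}"]
    if seed is not None:
        lines.append(f"# seed {seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        lines.append(f"# config_sha256 {digest}")
    return lines


def _write_tsv(df: pd.DataFrame, path, index: bool, seed=None, config=None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in _provenance_lines(seed, config):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", na_rep=MISSING, index=index)


def _features_path(path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".features.tsv")


def write_peak_matrix(pm: PeakMatrix, path, features_path=None,
                      seed=None, config=None) -> None:
    """Write injections table + companion feature-metadata TSV."""
    wide = pd.concat(
        [pm.samples.reset_index(drop=True), pm.values.reset_index(drop=True)], axis=1
    )
    _write_tsv(wide, path, index=False, seed=seed, config=config)
    _write_tsv(
        pm.features, features_path or _features_path(path), index=True,
        seed=seed, config=config,
    )


def read_peak_matrix(path, features_path=None) -> PeakMatrix:
    """Read and validate the TSV dialect written by ``write_peak_matrix``."""
    wide = pd.read_csv(path, sep="\t", comment="#", na_values=[MISSING])
    missing_cols = [c for c in SAMPLE_COLUMNS if c not in wide.columns]
    if missing_cols:
        raise ValidationError(f"peak matrix missing required columns: {missing_cols}")
    samples = wide[list(SAMPLE_COLUMNS)].copy()
    values = wide.drop(columns=list(SAMPLE_COLUMNS))
    features = None
    fpath = Path(features_path or _features_path(path))
    if fpath.exists():
        features = pd.read_csv(
            fpath, sep="\t", comment="#", na_values=[MISSING], index_col=0
        )
        extra = set(values.columns) - set(features.index.astype(str))
        if extra:
            raise ValidationError(
                f"features absent from metadata table: {sorted(extra)[:5]}"
            )
        features = features.loc[list(values.columns)]
    return PeakMatrix(samples=samples, values=values, features=features)


def write_cohort(cohort: pd.DataFrame, path, seed=None, config=None) -> None:
    _write_tsv(cohort, path, index=True, seed=seed, config=config)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort TSV; unknown columns are carried as
    clinical analytes."""
    table = pd.read_csv(
        path, sep="\t", comment="#", na_values=[MISSING], index_col="subject_id"
    )
    for col in ("age", "bmi", "sbp", "dbp"):
        if col in table.columns and not pd.api.types.is_numeric_dtype(table[col]):
            raise ValidationError(f"column {col!r} is not numeric")
    validate_cohort(table)
    return table


def write_integrated(matrix: IntegratedMatrix, prefix, seed=None, config=None) -> None:
    """Write subjects, QC-audit and feature tables as <prefix>.*.tsv."""
    prefix = Path(prefix)
    _write_tsv(matrix.values, prefix.with_suffix(".subjects.tsv"), index=True,
               seed=seed, config=config)
    _write_tsv(matrix.qc_values, prefix.with_suffix(".qc.tsv"), index=True,
               seed=seed, config=config)
    _write_tsv(matrix.features, prefix.with_suffix(".features.tsv"), index=True,
               seed=seed, config=config)


def read_integrated(prefix) -> IntegratedMatrix:
    prefix = Path(prefix)
    values = pd.read_csv(prefix.with_suffix(".subjects.tsv"), sep="\t",
                         comment="#", na_values=[MISSING], index_col=0)
    qc = pd.read_csv(prefix.with_suffix(".qc.tsv"), sep="\t",
                     comment="#", na_values=[MISSING], index_col=0)
    features = pd.read_csv(prefix.with_suffix(".features.tsv"), sep="\t",
                           comment="#", na_values=[MISSING], index_col=0)
    return IntegratedMatrix(values=values, qc_values=qc, features=features)
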