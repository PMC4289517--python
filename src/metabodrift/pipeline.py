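"""End-to-end pipeline orchestration driven by a YAML/dict configuration."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import ValidationError
from . import io as mio
from .cohort import generate_cohort
from .consensus import consensus_select
from .correction import LoessParams, correct_batch, fit_batch_curves
from .design import build_study_design
from .filters import information_filter, qa_filter
from .groups import hypothesis_labels
from .integrate import integrate_study
from .preprocess import autoscale, impute_missing
from .samplesize import accuracy_vs_n
from .simulate import (
    DriftModel,
    EffectSpec,
    MissingnessParams,
    make_feature_catalogue,
    simulate_study,
)
from .stats import univariate_screen

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Stage toggles and parameters; see module docstrings for semantics."""

    out_dir: str = "pipeline_out"
    seed: int | None = None
    platform: str = "UPLC_pos"
    # simulation
    simulate: bool = True
    n_batches: int = 2
    subjects_per_batch: int = 120
    subjects_per_run: int | None = None
    n_features: int = 50
    hypothesis: str = "gender"
    n_informative: int = 10
    effect_size: float = 1.0
    # inputs when simulation is off
    input_batches: list = field(default_factory=list)
    input_cohort: str | None = None
    # correction / QA
    correct: bool = True
    qa: bool = True
    loess_span_grid: tuple = (0.3, 0.5, 0.75, 1.0)
    # stats / selection / sample size
    stats: bool = True
    select: bool = True
    selection_B: int = 20
    selection_k_max: int = 20
    samplesize: bool = False
    samplesize_grid: tuple = ()
    samplesize_B: int = 20

    def __post_init__(self):
        stochastic = self.simulate or self.select or self.samplesize
        if stochastic and self.seed is None:
            raise ValidationError("a seed is required when stochastic stages run")
        if not self.simulate and not self.input_batches:
            raise ValidationError("no input batches and simulation disabled")


def _low_high(labels: pd.Series) -> tuple[str, str]:
    levels = sorted(set(labels.dropna()))
    return str(levels[0]), str(levels[-1])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the JSON-serializable run report.

    Artifacts (peak tables, integrated matrix, statistics, selection
    manifest) and the report are written under ``config.out_dir``.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "seed": config.seed, "config": asdict(config)}
    rng = np.random.default_rng(config.seed)

    if config.simulate:
        design = build_study_design(
            config.platform,
            n_batches=config.n_batches,
            subjects_per_batch=config.subjects_per_batch,
            subjects_per_run=config.subjects_per_run,
        )
        n_subjects = sum(b.n_subjects for b in design)
        cohort = generate_cohort(n_subjects, seed=rng)
        catalogue = make_feature_catalogue(config.n_features, config.platform, seed=rng)
        labels_full = hypothesis_labels(cohort, config.hypothesis)
        low, high = _low_high(labels_full)
        effects = (
            EffectSpec(
                factor=config.hypothesis,
                features=tuple(catalogue.index[: config.n_informative]),
                effect_size=config.effect_size,
                low_level=low,
                high_level=high,
            ),
        )
        batches, truth = simulate_study(
            design, cohort, catalogue, DriftModel(), effects,
            MissingnessParams(), seed=rng,
        )
        mio.write_cohort(cohort, out / "cohort.tsv", seed=config.seed)
        for b in batches:
            bid = b.samples["batch_id"].iloc[0]
            mio.write_peak_matrix(b, out / f"raw_{bid}.tsv", seed=config.seed)
        report["stages"]["simulate"] = {
            "n_batches": len(batches),
            "n_subjects": n_subjects,
            "n_features": config.n_features,
            "n_injections": int(sum(len(b.samples) for b in batches)),
        }
    else:
        batches = [mio.read_peak_matrix(p) for p in config.input_batches]
        cohort = mio.read_cohort(config.input_cohort) if config.input_cohort else None

    if config.correct:
        params = LoessParams(span_grid=tuple(config.loess_span_grid))
        corrected = []
        n_uncorrectable = 0
        for b in batches:
            curves, unc = fit_batch_curves(b, params)
            n_uncorrectable += len(unc)
            corrected.append(correct_batch(b, curves))
        integrated = integrate_study(corrected)
        mio.write_integrated(integrated, out / "integrated", seed=config.seed)
        report["stages"]["correct"] = {
            "n_uncorrectable_feature_runs": n_uncorrectable,
            "n_subject_rows": int(len(integrated.values)),
            "n_features": int(integrated.values.shape[1]),
        }
    else:
        integrated = None

    if config.qa:
        if integrated is None:
            raise ValidationError("qa stage requires the correction stage")
        integrated, qa_report = qa_filter(integrated, platform=config.platform)
        integrated, info_report = information_filter(integrated)
        qa_report.table.to_csv(out / "qa_report.tsv", sep="\t", na_rep="NA")
        (out / "qa_report.json").write_text(
            json.dumps(
                {
                    "qa": {"n_in": qa_report.n_in, "n_out": qa_report.n_out},
                    "information": {
                        "n_in": info_report.n_in,
                        "n_out": info_report.n_out,
                    },
                },
                indent=2,
            )
        )
        report["stages"]["qa"] = {
            "after_qa": qa_report.n_out,
            "after_information": info_report.n_out,
        }

    analysis = None
    labels = None
    if integrated is not None and cohort is not None:
        subjects = [s for s in integrated.values.index if s in cohort.index]
        analysis = autoscale(impute_missing(integrated.values.loc[subjects]))
        labels = hypothesis_labels(cohort.loc[subjects], config.hypothesis)
        keep = labels.notna()
        analysis, labels = analysis.loc[keep.to_numpy()], labels[keep]

    if config.stats and analysis is not None:
        screen = univariate_screen(analysis, labels)
        screen.to_csv(out / "univariate_screen.tsv", sep="\t", na_rep="NA")
        report["stages"]["stats"] = {
            "n_features_tested": int(len(screen)),
            "n_p_below_0.05": int((screen["pvalue"] < 0.05).sum()),
        }

    if config.select and analysis is not None:
        result = consensus_select(
            analysis, labels.to_numpy(), B=config.selection_B,
            k_max=min(config.selection_k_max, analysis.shape[1]),
            seed=config.seed,
        )
        manifest = {
            "hypothesis": config.hypothesis,
            "B": config.selection_B,
            "seed": config.seed,
            "k_star": result.curve.k_star,
            "selected_features": list(result.selected),
            "accuracy": result.comparison,
        }
        (out / "selection_manifest.json").write_text(json.dumps(manifest, indent=2))
        report["stages"]["select"] = {
            "k_star": result.curve.k_star,
            "n_selected": len(result.selected),
        }

    if config.samplesize and analysis is not None:
        sizes = tuple(config.samplesize_grid) or None
        curve = accuracy_vs_n(
            analysis, labels.to_numpy(), sizes=sizes,
            B=config.samplesize_B, seed=config.seed,
        )
        curve.to_csv(out / "samplesize_curve.tsv", sep="\t", index=False)
        report["stages"]["samplesize"] = {"n_sizes": int(curve["size"].nunique())}

    report["wall_clock_s"] = round(time.time() - t0, 3)
    (out / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
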