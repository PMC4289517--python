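import numpy as np
import pandas as pd
import pytest

import metabodrift as md
from metabodrift.simulate import DriftModel, MissingnessParams


@pytest.fixture(scope="session")
def small_study():
    """2 batches x 24 subjects x 12 features with mild drift; shared across
    tests that only read from it."""
    design = md.build_study_design(
        "UPLC_pos", n_batches=2, subjects_per_batch=20, subjects_per_run=20,
        n_conditioning=4,
    )
    cohort = md.generate_cohort(40, seed=11)
    catalogue = md.make_feature_catalogue(12, "UPLC_pos", seed=12)
    batches, truth = md.simulate_study(
        design, cohort, catalogue,
        DriftModel(attenuation=(0.1, 0.3), technical_cv=0.03),
        (), MissingnessParams(mnar_quantile=0.0, mcar_rate=0.0), seed=13,
    )
    return {"design": design, "cohort": cohort, "catalogue": catalogue,
            "batches": batches, "truth": truth}


@pytest.fixture(scope="session")
def clean_study():
    """Drift-free, noise-free study: correction must be an exact identity."""
    design = md.build_study_design(
        "UPLC_pos", n_batches=2, subjects_per_batch=20, subjects_per_run=20,
        n_conditioning=4,
    )
    cohort = md.generate_cohort(40, seed=21)
    catalogue = md.make_feature_catalogue(8, "UPLC_pos", seed=22)
    drift = DriftModel(
        attenuation=(0.0, 0.0), sin_amplitude=(0.0, 0.0),
        batch_step_sigma=0.0, technical_cv=0.0, biological_cv=0.4,
    )
    batches, truth = md.simulate_study(
        design, cohort, catalogue, drift, (), None, seed=23
    )
    return {"batches": batches, "truth": truth}
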