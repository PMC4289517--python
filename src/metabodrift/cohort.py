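"""Synthetic cohort generation calibrated to a healthy UK adult population.

Continuous demographics (age, BMI, blood pressures, clinical-chemistry
analytes) are drawn from quantile-matched split-normal distributions: the
population median and quartiles of each marginal equal the calibration
values by construction, while the two half-widths accommodate skew.
Categorical traits (gender, smoking status) are multinomial draws with the
calibrated frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from ._utils import ValidationError, check_rng

_Z75 = norm.ppf(0.75)  # 0.6744897...

SMOKING_LEVELS = ("non", "ex", "current")
GENDER_LEVELS = ("male", "female")


@dataclass(frozen=True)
class QuantileSpec:
    """Median/IQR calibration for one continuous marginal, with hard bounds.

    The distribution is a two-piece (split) normal with each half truncated
    at the corresponding bound; the half-scales are calibrated numerically
    so the truncated distribution's median and quartiles equal the stated
    values exactly.
    """

    median: float
    q1: float
    q3: float
    lo: float = -np.inf
    hi: float = np.inf

    def __post_init__(self):
        if not (self.q1 < self.median < self.q3):
            raise ValidationError(
                f"inverted quantiles: q1={self.q1}, median={self.median}, q3={self.q3}"
            )
        if not (self.lo < self.q1 and self.q3 < self.hi):
            raise ValidationError("quartiles must lie strictly inside [lo, hi]")
        # calibrate each truncated half so that ppf(0.25) = q1, ppf(0.75) = q3
        object.__setattr__(
            self,
            "sigma_lo",
            _calibrate_half(self.median - self.q1, self.median - self.lo),
        )
        object.__setattr__(
            self,
            "sigma_hi",
            _calibrate_half(self.q3 - self.median, self.hi - self.median),
        )

    def ppf(self, u) -> np.ndarray:
        """Quantile function; maps [0, 1] onto [lo, hi] with the calibrated
        median and quartiles."""
        u = np.asarray(u, dtype=float)
        a = norm.cdf((self.lo - self.median) / self.sigma_lo)
        b = norm.cdf((self.hi - self.median) / self.sigma_hi)
        low = self.median + self.sigma_lo * norm.ppf(a + 2 * u * (0.5 - a))
        high = self.median + self.sigma_hi * norm.ppf(
            0.5 + 2 * (u - 0.5) * (b - 0.5)
        )
        return np.where(u < 0.5, low, high)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.ppf(rng.uniform(size=n))


def _calibrate_half(quartile_gap: float, bound_gap: float) -> float:
    """Scale of one truncated-normal half such that its within-half median
    (the overall quartile) sits ``quartile_gap`` from the centre given the
    truncation ``bound_gap`` away."""
    if not np.isfinite(bound_gap):
        return quartile_gap / _Z75
    if quartile_gap >= bound_gap / 2:
        raise ValidationError(
            "quartile too close to the bound for a truncated-normal half"
        )

    def f(sigma: float) -> float:
        c = norm.cdf(bound_gap / sigma)
        return sigma * norm.ppf((0.5 + c) / 2.0) - quartile_gap

    lo = quartile_gap / _Z75  # untruncated solution; truncation needs sigma >= this
    hi = lo
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e6 * lo:  # pragma: no cover - guarded by the gap check above
            raise ValidationError("half-scale calibration failed to bracket")
    return float(brentq(f, lo * 0.999, hi))


# Calibration of the default cohort: medians and IQRs of the reference
# population of 1,200 healthy adults (ages 19-81).
DEFAULT_DEMOGRAPHICS: dict = {
    "age": QuantileSpec(48.0, 40.0, 60.0, lo=19.0, hi=81.0),
    "bmi": QuantileSpec(25.63, 23.20, 28.71, lo=14.0, hi=60.0),
    "sbp": QuantileSpec(125.0, 115.0, 137.0, lo=70.0, hi=230.0),
    "dbp": QuantileSpec(76.0, 70.0, 83.0, lo=40.0, hi=140.0),
    "male_fraction": 701 / 1191,
    "smoking_counts": {"non": 502, "ex": 163, "current": 176},
}

# 5 of the 23 routine clinical-chemistry assays, mmol/L (the remainder of
# the panel can be supplied through `clinical_specs`).
DEFAULT_CLINICAL: dict[str, QuantileSpec] = {
    "GLUC": QuantileSpec(4.71, 4.20, 5.30, lo=0.0),
    "CHOL": QuantileSpec(5.10, 4.30, 5.80, lo=0.0),
    "TRIG": QuantileSpec(1.18, 0.80, 1.80, lo=0.0),
    "HDLC": QuantileSpec(1.26, 1.00, 1.50, lo=0.0),
    "LDLC": QuantileSpec(3.2, 2.54, 3.77, lo=0.0),
}

CLINICAL_COLUMNS = tuple(DEFAULT_CLINICAL)
DEMOGRAPHIC_COLUMNS = ("age", "gender", "bmi", "sbp", "dbp", "smoking")


def generate_cohort(
    n: int,
    demographic_params: dict | None = None,
    seed=None,
    include_clinical: bool = True,
    clinical_specs: dict[str, QuantileSpec] | None = None,
    correlations: dict[tuple[str, str], float] | None = None,
) -> pd.DataFrame:
    """Generate a synthetic subject table.

    Parameters
    ----------
    n : int
        Number of subjects (>= 0).
    demographic_params : dict, optional
        Overrides for ``DEFAULT_DEMOGRAPHICS`` entries.
    seed : int, Generator, optional
        Randomness source; the same seed reproduces the table exactly.
    include_clinical : bool
        Attach the clinical-chemistry panel columns.
    clinical_specs : dict, optional
        Extra/override analyte ``QuantileSpec``s.

    Returns
    -------
    DataFrame indexed by unique ``subject_id`` with columns
    age, gender, bmi, sbp, dbp, smoking and optional clinical analytes.
    SBP > DBP is enforced per subject by paired rejection sampling.
    """
    if n < 0:
        raise ValidationError(f"cohort size must be >= 0, got {n}")
    params = dict(DEFAULT_DEMOGRAPHICS)
    if demographic_params:
        params.update(demographic_params)
    for key in ("age", "bmi", "sbp", "dbp"):
        if not isinstance(params[key], QuantileSpec):
            raise ValidationError(f"demographic_params[{key!r}] must be a QuantileSpec")
    rng = check_rng(seed)

    subject_id = [f"S{i + 1:05d}" for i in range(n)]

    continuous: dict[str, QuantileSpec] = {
        k: params[k] for k in ("age", "bmi", "sbp", "dbp")
    }
    if include_clinical:
        specs = dict(DEFAULT_CLINICAL)
        if clinical_specs:
            specs.update(clinical_specs)
        continuous.update(specs)

    if correlations:
        draws = _copula_sample(continuous, correlations, n, rng)
    else:
        draws = {name: spec.sample(n, rng) for name, spec in continuous.items()}

    gender = np.where(
        rng.uniform(size=n) < params["male_fraction"], "male", "female"
    )
    sbp, dbp = draws["sbp"], draws["dbp"]
    bad = sbp <= dbp
    while bad.any():
        idx = np.flatnonzero(bad)
        sbp[idx] = params["sbp"].sample(idx.size, rng)
        dbp[idx] = params["dbp"].sample(idx.size, rng)
        bad = sbp <= dbp

    counts = params["smoking_counts"]
    p = np.array([counts[k] for k in SMOKING_LEVELS], dtype=float)
    smoking = rng.choice(SMOKING_LEVELS, size=n, p=p / p.sum())

    table = pd.DataFrame(
        {
            "age": draws["age"],
            "gender": gender,
            "bmi": draws["bmi"],
            "sbp": sbp,
            "dbp": dbp,
            "smoking": smoking,
        },
        index=pd.Index(subject_id, name="subject_id"),
    )
    for name in continuous:
        if name not in table.columns:
            table[name] = draws[name]
    return table


def _copula_sample(
    specs: dict[str, QuantileSpec],
    correlations: dict[tuple[str, str], float],
    n: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Gaussian-copula draw of the continuous marginals.

    Optional hook: marginals stay quantile-matched while selected pairs get
    the requested latent correlation. Out-of-bound values are clipped (not
    rejected) so the joint structure is preserved.
    """
    names = list(specs)
    k = len(names)
    corr = np.eye(k)
    for (a, b), rho in correlations.items():
        if a not in specs or b not in specs:
            raise ValidationError(f"unknown correlation pair ({a}, {b})")
        if not -1.0 < rho < 1.0:
            raise ValidationError(f"correlation out of (-1, 1): {rho}")
        i, j = names.index(a), names.index(b)
        corr[i, j] = corr[j, i] = rho
    if np.linalg.eigvalsh(corr).min() <= 0:
        raise ValidationError("requested correlation matrix is not positive definite")
    z = rng.multivariate_normal(np.zeros(k), corr, size=n, method="cholesky")
    u = norm.cdf(z)
    return {
        name: np.clip(specs[name].ppf(u[:, i]), specs[name].lo, specs[name].hi)
        for i, name in enumerate(names)
    }


def validate_cohort(table: pd.DataFrame) -> None:
    """Check the cohort invariants; raise ValidationError on violation."""
    if table.index.has_duplicates:
        raise ValidationError("duplicate subject_id")
    if len(table) == 0:
        return
    if (table["bmi"] <= 0).any():
        raise ValidationError("non-positive BMI")
    if (table["sbp"] <= table["dbp"]).any():
        raise ValidationError("SBP must exceed DBP for every subject")
    bad = set(table["smoking"].dropna()) - set(SMOKING_LEVELS)
    if bad:
        raise ValidationError(f"unknown smoking categories: {sorted(bad)}")
    bad = set(table["gender"].dropna()) - set(GENDER_LEVELS)
    if bad:
        raise ValidationError(f"unknown gender categories: {sorted(bad)}")
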