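"""Clinical-hypothesis group labels derived from the cohort table.

Boundary conventions: age bins are [min,40), [40,50), [50,65), [65,max];
the binary age contrast is <50 vs >64; BMI <25 vs >30 with the middle
excluded; blood pressure normal = systolic in [90,120] vs hypertensive
>140 mmHg, middle excluded. Subjects falling in no bin get NaN and are
excluded from that hypothesis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._utils import ValidationError

HYPOTHESES = ("gender", "age4", "age2", "bmi2", "bp2", "smoking")


def hypothesis_labels(cohort: pd.DataFrame, hypothesis: str) -> pd.Series:
    """Return a per-subject categorical label Series (NaN = excluded)."""
    if hypothesis == "gender":
        return cohort["gender"].astype("object")
    if hypothesis == "age4":
        age = cohort["age"]
        bins = [-np.inf, 40, 50, 65, np.inf]
        labels = ["<40", "40-49", "50-64", ">64"]
        return pd.Series(
            pd.cut(age, bins=bins, labels=labels, right=False).astype("object"),
            index=cohort.index,
        )
    if hypothesis == "age2":
        age = cohort["age"]
        out = pd.Series(np.nan, index=cohort.index, dtype="object")
        out[age < 50] = "<50"
        out[age > 64] = ">64"
        return out
    if hypothesis == "bmi2":
        bmi = cohort["bmi"]
        out = pd.Series(np.nan, index=cohort.index, dtype="object")
        out[bmi < 25] = "<25"
        out[bmi > 30] = ">30"
        return out
    if hypothesis == "bp2":
        sbp = cohort["sbp"]
        out = pd.Series(np.nan, index=cohort.index, dtype="object")
        out[(sbp >= 90) & (sbp <= 120)] = "normal"
        out[sbp > 140] = "hypertensive"
        return out
    if hypothesis == "smoking":
        return cohort["smoking"].astype("object")
    if hypothesis in cohort.columns:
        return cohort[hypothesis].astype("object")
    raise ValidationError(
        f"unknown hypothesis {hypothesis!r}; expected one of {HYPOTHESES} "
        "or a cohort column"
    )
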