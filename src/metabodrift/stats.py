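"""Univariate screens, two-way ANOVA with Tukey HSD, correlation clustering.

The screens are rank-based (Mann-Whitney U for two groups, Kruskal-Wallis
beyond), so their p-values are invariant under monotone transforms of the
data. Two-way ANOVA uses Type II sums of squares, the standard choice for
unbalanced observational designs without strong interactions. Tukey's HSD
uses the exact studentized-range distribution. Correlation heatmap
ordering comes from average-linkage hierarchical clustering on the
1 - |r| distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as ss
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from ._utils import ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- screens

def _group_arrays(x: np.ndarray, labels: pd.Series) -> list[np.ndarray]:
    lab = pd.Series(labels).astype("object")
    keep = lab.notna().to_numpy()
    x, lab = x[keep], lab[keep]
    groups = [x[(lab == g).to_numpy()] for g in pd.unique(lab)]
    if len(groups) < 2:
        raise ValidationError("need >= 2 non-empty groups")
    if any(g.size == 0 for g in groups):
        raise ValidationError("empty group")
    return groups


def univariate_screen(
    matrix: pd.DataFrame,
    labels: pd.Series,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-feature two-sided Mann-Whitney U (2 groups) or Kruskal-Wallis (>2).

    Exact Mann-Whitney p-values are used for small tie-free samples, the
    tie-corrected normal approximation otherwise (scipy's ``method="auto"``
    policy). Groups with fewer than 2 members trigger a warning and force
    the exact method. No multiple-testing correction is applied unless
    ``fdr=True``, which adds a Benjamini-Hochberg ``qvalue`` column.
    """
    stats, pvals = [], []
    for fid in matrix.columns:
        groups = _group_arrays(matrix[fid].to_numpy(dtype=float), labels)
        if any(g.size < 2 for g in groups):
            logger.warning("feature %s: a group has < 2 members; exact test", fid)
        if len(groups) == 2:
            method = "exact" if any(g.size < 2 for g in groups) else "auto"
            res = ss.mannwhitneyu(
                groups[0], groups[1], alternative="two-sided", method=method
            )
        else:
            res = ss.kruskal(*groups)
        stats.append(float(res.statistic))
        pvals.append(float(res.pvalue))
    out = pd.DataFrame({"statistic": stats, "pvalue": pvals}, index=matrix.columns)
    if fdr:
        out["qvalue"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out


# ------------------------------------------------------------------ ANOVA

@dataclass(frozen=True)
class FactorEffect:
    name: str
    F: float
    df_num: int
    df_den: int
    pvalue: float


@dataclass(frozen=True)
class AnovaResult:
    """Main effects and interaction of a (possibly unbalanced) two-way ANOVA."""

    factor_a: FactorEffect
    factor_b: FactorEffect
    interaction: FactorEffect | None

    def as_frame(self) -> pd.DataFrame:
        rows = [self.factor_a, self.factor_b]
        if self.interaction is not None:
            rows.append(self.interaction)
        return pd.DataFrame(
            [(e.name, e.F, e.df_num, e.df_den, e.pvalue) for e in rows],
            columns=["effect", "F", "df_num", "df_den", "pvalue"],
        )


def two_way_anova(
    values,
    factor_a,
    factor_b,
    interaction: bool = True,
    names: tuple[str, str] = ("A", "B"),
) -> AnovaResult:
    """Two-way ANOVA via an OLS fit with Type II sums of squares.

    Rows with a missing value or label are dropped. Requires two or more
    levels per factor; when the interaction is requested every factor-level
    cell must be non-empty.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(values, dtype=float),
            "a": pd.Series(factor_a).astype("object").to_numpy(),
            "b": pd.Series(factor_b).astype("object").to_numpy(),
        }
    ).dropna()
    for col in ("a", "b"):
        if df[col].nunique() < 2:
            raise ValidationError(f"factor {col!r} needs >= 2 levels")
    if interaction:
        cells = df.groupby(["a", "b"], observed=True).size()
        expected = df["a"].nunique() * df["b"].nunique()
        if len(cells) < expected:
            raise ValidationError(
                "empty factor-level cell; refit with interaction=False"
            )
    formula = "y ~ C(a) * C(b)" if interaction else "y ~ C(a) + C(b)"
    model = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    df_den = int(table.loc["Residual", "df"])

    def effect(row: str, label: str) -> FactorEffect:
        return FactorEffect(
            name=label,
            F=float(table.loc[row, "F"]),
            df_num=int(table.loc[row, "df"]),
            df_den=df_den,
            pvalue=float(table.loc[row, "PR(>F)"]),
        )

    return AnovaResult(
        factor_a=effect("C(a)", names[0]),
        factor_b=effect("C(b)", names[1]),
        interaction=effect("C(a):C(b)", f"{names[0]}:{names[1]}")
        if interaction
        else None,
    )


def anova_screen(
    matrix: pd.DataFrame,
    factor_a,
    factor_b,
    interaction: bool = True,
    names: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Two-way ANOVA for every feature; long-format results table."""
    frames = []
    for fid in matrix.columns:
        res = two_way_anova(matrix[fid], factor_a, factor_b, interaction, names)
        frame = res.as_frame()
        frame.insert(0, "feature_id", fid)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def tukey_hsd(values, factor) -> pd.DataFrame:
    """All pairwise comparisons with studentized-range adjusted p-values.

    To compare levels of one factor "independent of" another (e.g. age
    groups independent of gender), pass the data collapsed over the other
    factor. Each level needs at least 2 observations and the residual df
    must be positive.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(values, dtype=float),
            "g": pd.Series(factor).astype("object").to_numpy(),
        }
    ).dropna()
    levels = list(pd.unique(df["g"]))
    if len(levels) < 2:
        raise ValidationError("Tukey HSD needs >= 2 levels")
    groups = [df.loc[df["g"] == g, "y"].to_numpy() for g in levels]
    if any(g.size < 2 for g in groups):
        raise ValidationError("every level needs >= 2 observations")
    if sum(g.size for g in groups) - len(groups) < 1:
        raise ValidationError("residual degrees of freedom < 1")
    res = ss.tukey_hsd(*groups)
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            rows.append(
                (
                    levels[i],
                    levels[j],
                    float(res.statistic[i, j]),
                    float(res.pvalue[i, j]),
                )
            )
    return pd.DataFrame(rows, columns=["level_1", "level_2", "diff", "pvalue"])


# ----------------------------------------------------------- correlations

@dataclass
class CorrelationResult:
    """Pearson coefficients with hierarchical-cluster leaf orders."""

    corr: pd.DataFrame
    row_order: list
    col_order: list
    row_linkage: np.ndarray | None = None
    col_linkage: np.ndarray | None = None

    def reordered(self) -> pd.DataFrame:
        return self.corr.loc[self.row_order, self.col_order]


def _abs_corr_linkage(data: pd.DataFrame):
    """Average-linkage tree on 1 - |pearson r| between the columns of data."""
    r = data.corr(method="pearson").to_numpy()
    d = 1.0 - np.abs(r)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    condensed = d[np.triu_indices_from(d, k=1)]
    link = sch.linkage(condensed, method="average")
    order = sch.leaves_list(link)
    return link, order


def correlation_cluster(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame | None = None,
    top_k: int | None = None,
) -> CorrelationResult:
    """Pairwise Pearson correlations with cluster-ordered axes.

    One matrix gives the square feature-feature map; two matrices give the
    rectangular feature-vs-clinical-chemistry map (pairwise-complete
    observations). Zero-variance variables are dropped with a log message.
    ``top_k`` restricts a square map to the k variables carrying the
    highest off-diagonal |r| (ties broken by variable order).
    """
    def drop_constant(m: pd.DataFrame, tag: str) -> pd.DataFrame:
        sd = m.std(ddof=1)
        bad = sd.index[(sd == 0) | sd.isna()]
        if len(bad):
            logger.info("dropping %d zero-variance %s variables", len(bad), tag)
            m = m.drop(columns=bad)
        if m.shape[1] < 2:
            raise ValidationError(f"need >= 2 usable {tag} variables")
        return m

    a = drop_constant(matrix_a, "row")
    if matrix_b is None:
        corr = a.corr(method="pearson")
        if top_k is not None and top_k < corr.shape[0]:
            off = corr.abs().to_numpy()
            np.fill_diagonal(off, -np.inf)
            best = pd.Series(off.max(axis=1), index=corr.index)
            keep = best.sort_values(ascending=False, kind="stable").index[:top_k]
            keep = [c for c in corr.columns if c in set(keep)]
            a = a[keep]
            corr = corr.loc[keep, keep]
        link, order = _abs_corr_linkage(a)
        names = list(corr.index)
        ordered = [names[i] for i in order]
        return CorrelationResult(corr, ordered, ordered, link, link)

    b = drop_constant(matrix_b, "column")
    joint = pd.concat([a, b], axis=1)
    corr = joint.corr(method="pearson").loc[a.columns, b.columns]
    row_link, row_order = _abs_corr_linkage(a)
    col_link, col_order = _abs_corr_linkage(b)
    return CorrelationResult(
        corr,
        [list(a.columns)[i] for i in row_order],
        [list(b.columns)[i] for i in col_order],
        row_link,
        col_link,
    )
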