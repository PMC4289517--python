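"""Empirical sample-size study: classification accuracy and feature-ranking
consistency as functions of subsample size.

For each size n on the grid (default 50..650 in steps of 50), B stratified
bootstrap sample sets of size n are drawn; a classifier (random forest or
RBF support-vector machine) is trained on each set and its accuracy
measured on the unsampled remainder, yielding the median accuracy and a
95 % percentile confidence interval per size. Ranking consistency at size
n is the Spearman correlation between the Borda-aggregated full ranking
computed on an n-sized subsample and the one computed on the full data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as ss
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from ._utils import ValidationError, check_rng, sklearn_seed
from .consensus import (
    RANKER_METHODS,
    borda_aggregate,
    bootstrap_rankings,
)

DEFAULT_SIZES = tuple(range(50, 651, 50))
SVM_COST_GRID = (0.1, 1.0, 10.0)


def default_sizes(n_available: int | None = None) -> tuple:
    """The 50..650 step-50 grid, truncated to the available sample count."""
    if n_available is None:
        return DEFAULT_SIZES
    return tuple(s for s in DEFAULT_SIZES if s <= n_available)


def _make_classifier(name: str, X, y, rng, rf_trees: int):
    if name == "random_forest":
        return lambda: RandomForestClassifier(
            n_estimators=rf_trees, random_state=sklearn_seed(rng), n_jobs=1
        )
    if name == "svm":
        # RBF kernel, default-heuristic bandwidth; the cost is picked once
        # by 3-fold CV on the largest subsample so per-size tuning cannot
        # confound the learning curve
        best_c, best = 1.0, -np.inf
        kf = StratifiedKFold(n_splits=3, shuffle=True, random_state=sklearn_seed(rng))
        for c in SVM_COST_GRID:
            score = cross_val_score(
                SVC(kernel="rbf", gamma="scale", C=c), X, y, cv=kf
            ).mean()
            if score > best:
                best_c, best = c, score
        return lambda: SVC(kernel="rbf", gamma="scale", C=best_c)
    raise ValidationError(f"unknown classifier {name!r}")


def _stratified_size_n(y: np.ndarray, n: int, rng, replace: bool) -> np.ndarray:
    """Draw n samples stratified by class (proportional allocation)."""
    classes, counts = np.unique(y, return_counts=True)
    alloc = np.floor(n * counts / counts.sum()).astype(int)
    alloc[alloc == 0] = 1
    while alloc.sum() < n:
        alloc[np.argmax(counts - alloc)] += 1
    while alloc.sum() > n:
        alloc[np.argmax(alloc)] -= 1
    parts = []
    for cls, k in zip(classes, alloc):
        members = np.flatnonzero(y == cls)
        if not replace and k > members.size:
            raise ValidationError("stratum smaller than requested draw")
        parts.append(rng.choice(members, size=k, replace=replace))
    return np.concatenate(parts)


def accuracy_vs_n(
    matrix,
    labels,
    sizes=None,
    classifiers: tuple = ("random_forest", "svm"),
    B: int = 100,
    rf_trees: int = 100,
    seed=None,
) -> pd.DataFrame:
    """Learning curves: median accuracy and 95 % CI per subsample size.

    Each of the B bootstrap sample sets at size n is a stratified draw
    with replacement; the trained classifier is evaluated on the samples
    not drawn. Returns a long DataFrame with columns size, classifier,
    median, ci_lo, ci_hi, n_resamples.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    n_total = len(y)
    sizes = tuple(sizes) if sizes is not None else default_sizes(n_total)
    if any(s > n_total for s in sizes):
        raise ValidationError("a requested size exceeds the population")
    if any(np.diff(sizes) <= 0):
        raise ValidationError("sizes must be strictly increasing")
    rng = check_rng(seed)

    rows = []
    for name in classifiers:
        factory = _make_classifier(name, X, y, rng, rf_trees)
        for n in sizes:
            accs = []
            for _ in range(B):
                idx = _stratified_size_n(y, n, rng, replace=True)
                test = np.setdiff1d(np.arange(n_total), idx)
                if test.size == 0 or np.unique(y[test]).size < 2:
                    continue
                clf = factory()
                clf.fit(X[idx], y[idx])
                accs.append(float(np.mean(clf.predict(X[test]) == y[test])))
            accs = np.array(accs)
            rows.append(
                {
                    "size": n,
                    "classifier": name,
                    "median": float(np.median(accs)),
                    "ci_lo": float(np.percentile(accs, 2.5)),
                    "ci_hi": float(np.percentile(accs, 97.5)),
                    "n_resamples": len(accs),
                }
            )
    return pd.DataFrame(rows)


def ranking_consistency_vs_n(
    matrix,
    labels,
    sizes=None,
    rankers: tuple = RANKER_METHODS,
    B: int = 25,
    rf_trees: int = 100,
    seed=None,
) -> pd.DataFrame:
    """Spearman correlation of subsample consensus rankings with the
    full-data consensus ranking, per subsample size.

    At n equal to the full sample count the subsample is the full data and
    the correlation is exactly 1.
    """
    X = np.asarray(matrix, dtype=float)
    feature_ids = (
        list(matrix.columns) if isinstance(matrix, pd.DataFrame)
        else list(range(X.shape[1]))
    )
    y = np.asarray(labels)
    n_total = len(y)
    sizes = tuple(sizes) if sizes is not None else default_sizes(n_total)
    if any(s > n_total for s in sizes):
        raise ValidationError("a requested size exceeds the population")
    master = np.random.SeedSequence(seed)
    streams = master.spawn(len(sizes) + 1)

    def aggregated_ranking(Xs, ys, stream) -> pd.Series:
        child = stream.spawn(len(rankers))
        lists = []
        frame = pd.DataFrame(Xs, columns=feature_ids)
        for method, cs in zip(rankers, child):
            lists.extend(
                bootstrap_rankings(
                    frame, ys, method, B=B,
                    seed=np.random.default_rng(cs), rf_trees=rf_trees,
                )
            )
        ranking = borda_aggregate(lists)
        return ranking.rank_of().loc[feature_ids]

    full_ranks = aggregated_ranking(X, y, streams[-1])

    rows = []
    for n, stream in zip(sizes, streams[: len(sizes)]):
        if n == n_total:
            rows.append({"size": n, "spearman": 1.0})
            continue
        rng = np.random.default_rng(stream)
        idx = _stratified_size_n(y, n, rng, replace=False)
        sub_ranks = aggregated_ranking(X[idx], y[idx], stream.spawn(1)[0])
        rho = ss.spearmanr(full_ranks.to_numpy(), sub_ranks.to_numpy()).statistic
        rows.append({"size": n, "spearman": float(rho)})
    return pd.DataFrame(rows)
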