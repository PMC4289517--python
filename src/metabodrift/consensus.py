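"""Bootstrap consensus feature selection with Borda-count aggregation.

Three ranker families — a rank-based univariate screen, random-forest
impurity importance, and PLS-DA VIP scores — are each fitted on B
stratified bootstrap resamples, every fit emitting a full importance
ranking of the candidate features. The 3 x B ranked lists are aggregated
by Borda count (a list of m features awards m - rank points to the feature
at each rank), yielding a single consensus ranking that is robust to the
idiosyncrasies of any one model family or resample. Forward-selection
remodeling then walks down the consensus list, retraining a classifier on
the top-k features, and selects k* at the inflection point of the
accuracy-versus-k curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as ss
from sklearn.base import BaseEstimator, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from ._utils import ValidationError, check_rng, sklearn_seed

logger = logging.getLogger(__name__)

RANKER_METHODS = ("univariate", "random_forest", "plsda")


# ----------------------------------------------------------------- types

@dataclass(frozen=True)
class RankedList:
    """A full importance ranking of the candidate features (rank 1 first)."""

    features: tuple
    method: str
    bootstrap_index: int

    def __post_init__(self):
        if len(set(self.features)) != len(self.features):
            raise ValidationError("ranked list contains duplicates")


@dataclass
class ConsensusRanking:
    """Borda-aggregated ranking: scores, descending order, tie audit."""

    order: tuple
    scores: pd.Series
    mean_ranks: pd.Series
    ties: list = field(default_factory=list)

    def rank_of(self) -> pd.Series:
        """1-based consensus rank per feature id."""
        return pd.Series(np.arange(1, len(self.order) + 1), index=list(self.order))


@dataclass
class SelectionCurve:
    """Accuracy of the classifier on the top-k consensus features."""

    k: np.ndarray
    accuracy: np.ndarray  # .632 bootstrap estimate per k
    dispersion: np.ndarray  # SD of the out-of-bag accuracies per k
    k_star: int
    accuracy_at_k_star: float


# --------------------------------------------------------------- rankers

def stratified_bootstrap_indices(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Bootstrap resample preserving exact class counts."""
    idx_parts = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        idx_parts.append(rng.choice(members, size=members.size, replace=True))
    return np.concatenate(idx_parts)


def _rank_univariate(X: np.ndarray, y: np.ndarray, rng) -> np.ndarray:
    classes = np.unique(y)
    if classes.size == 2:
        a, b = X[y == classes[0]], X[y == classes[1]]
        res = ss.mannwhitneyu(a, b, alternative="two-sided",
                              method="asymptotic", axis=0)
        return -np.asarray(res.pvalue)
    scores = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        scores[j] = -ss.kruskal(*(X[y == c, j] for c in classes)).pvalue
    return scores


def _rank_random_forest(X, y, rng, n_estimators=100) -> np.ndarray:
    rf = RandomForestClassifier(
        n_estimators=n_estimators, random_state=sklearn_seed(rng), n_jobs=1
    )
    rf.fit(X, y)
    return rf.feature_importances_


def _vip_scores(pls: PLSRegression) -> np.ndarray:
    t, w, q = pls.x_scores_, pls.x_weights_, pls.y_loadings_
    p, a = w.shape
    s = np.sum(t**2, axis=0) * np.sum(q**2, axis=0)
    wnorm = w / np.linalg.norm(w, axis=0, keepdims=True)
    return np.sqrt(p * (wnorm**2 @ s) / s.sum())


def choose_plsda_components(
    X: np.ndarray, y: np.ndarray, candidates=(2, 3, 4, 5), seed=0
) -> int:
    """Pick the PLS-DA latent-variable count once by 3-fold CV R^2 on the
    class indicator."""
    Y = _one_hot(y)
    best, best_score = candidates[0], -np.inf
    cap = max(1, min(X.shape[1], X.shape[0] - 2))
    kf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    for nc in candidates:
        if nc > cap:
            continue
        scores = []
        for tr, te in kf.split(X, y):
            pls = PLSRegression(n_components=nc).fit(X[tr], Y[tr])
            resid = Y[te] - pls.predict(X[te])
            scores.append(-np.mean(resid**2))
        score = float(np.mean(scores))
        if score > best_score:
            best, best_score = nc, score
    return best


def _one_hot(y: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    if classes.size == 2:
        return np.where(y == classes[1], 1.0, -1.0)[:, None]
    return (y[:, None] == classes[None, :]).astype(float)


def _rank_plsda(X, y, rng, n_components=2) -> np.ndarray:
    nc = min(n_components, X.shape[1], X.shape[0] - 1)
    pls = PLSRegression(n_components=nc)
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    pls.fit(Xc / sd, _one_hot(y))
    return _vip_scores(pls)


def bootstrap_rankings(
    matrix,
    labels,
    method: str,
    B: int = 100,
    seed=None,
    n_components: int | None = None,
    rf_trees: int = 100,
) -> list[RankedList]:
    """B stratified-bootstrap rankings from one ranker family.

    ``method`` is one of 'univariate', 'random_forest', 'plsda'. The
    stratified resample preserves class counts, so no class can vanish
    from a resample; a defensive redraw is retained regardless. Ties in
    the importance scores are broken by column order (stable argsort), so
    the output is deterministic given the seed.
    """
    if method not in RANKER_METHODS:
        raise ValidationError(f"unknown ranker {method!r}; expected {RANKER_METHODS}")
    if B < 1:
        raise ValidationError("B must be >= 1")
    X = np.asarray(matrix, dtype=float)
    feature_ids = (
        tuple(matrix.columns) if isinstance(matrix, pd.DataFrame)
        else tuple(range(X.shape[1]))
    )
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValidationError("labels must contain >= 2 classes")
    rng = check_rng(seed)

    if method == "plsda" and n_components is None:
        n_components = choose_plsda_components(X, y, seed=sklearn_seed(rng))

    rankers = {
        "univariate": _rank_univariate,
        "random_forest": lambda X_, y_, r: _rank_random_forest(
            X_, y_, r, n_estimators=rf_trees
        ),
        "plsda": lambda X_, y_, r: _rank_plsda(X_, y_, r, n_components=n_components),
    }
    ranker = rankers[method]

    out = []
    for b in range(B):
        for _attempt in range(100):
            idx = stratified_bootstrap_indices(y, rng)
            if np.unique(y[idx]).size == np.unique(y).size:
                break
            logger.info("bootstrap %d lost a class; redrawn", b)
        scores = ranker(X[idx], y[idx], rng)
        order = np.argsort(-scores, kind="stable")
        out.append(
            RankedList(
                features=tuple(feature_ids[j] for j in order),
                method=method,
                bootstrap_index=b,
            )
        )
    return out


# ----------------------------------------------------------------- Borda

def borda_aggregate(lists: list[RankedList]) -> ConsensusRanking:
    """Borda-count aggregation of full ranked lists.

    Each list of m features awards ``m - rank`` points (rank is 1-based,
    so the top feature gets m - 1 and the last gets 0); points are summed
    over lists and features ordered by descending score. Ties are broken
    by ascending mean rank, then lexically by feature id, and recorded.
    """
    if not lists:
        raise ValidationError("no ranked lists to aggregate")
    universe = frozenset(lists[0].features)
    m = len(universe)
    for rl in lists:
        if frozenset(rl.features) != universe:
            raise ValidationError("ranked lists cover different feature sets")
    score: dict = {f: 0.0 for f in universe}
    rank_sum: dict = {f: 0.0 for f in universe}
    for rl in lists:
        for rank0, f in enumerate(rl.features):
            score[f] += m - (rank0 + 1)
            rank_sum[f] += rank0 + 1
    mean_rank = {f: rank_sum[f] / len(lists) for f in universe}
    order = sorted(universe, key=lambda f: (-score[f], mean_rank[f], str(f)))
    ties = [
        sorted(group, key=str)
        for s, group in pd.Series(score).groupby(pd.Series(score)).groups.items()
        if len(group) > 1
    ]
    return ConsensusRanking(
        order=tuple(order),
        scores=pd.Series(score).loc[list(order)],
        mean_ranks=pd.Series(mean_rank).loc[list(order)],
        ties=ties,
    )


# ------------------------------------------------------ forward selection

def _accuracy_632(
    X: np.ndarray, y: np.ndarray, classifier, n_resamples: int, rng
) -> tuple[float, float]:
    """The .632+ bootstrap accuracy estimate, plus the SD of the
    out-of-bag accuracies.

    The plain .632 estimator (0.368 resubstitution + 0.632 out-of-bag) is
    badly optimistic for interpolating classifiers like a random forest,
    whose resubstitution error is ~0; the .632+ variant shifts the weight
    toward the out-of-bag error according to the relative overfitting rate
    against the no-information rate, so null data score at chance.
    """
    clf = clone(classifier)
    if "random_state" in clf.get_params():
        clf.set_params(random_state=sklearn_seed(rng))
    clf.fit(X, y)
    pred_full = clf.predict(X)
    err_resub = float(np.mean(pred_full != y))
    # no-information error rate: expected error if predictions and labels
    # were independent
    classes = np.unique(y)
    p = np.array([np.mean(y == c) for c in classes])
    q = np.array([np.mean(pred_full == c) for c in classes])
    gamma = float(np.sum(p * (1.0 - q)))

    oob = []
    n = len(y)
    for _ in range(n_resamples):
        idx = stratified_bootstrap_indices(y, rng)
        test = np.setdiff1d(np.arange(n), idx)
        if test.size == 0 or np.unique(y[test]).size < np.unique(y).size:
            continue
        clf = clone(classifier)
        if "random_state" in clf.get_params():
            clf.set_params(random_state=sklearn_seed(rng))
        clf.fit(X[idx], y[idx])
        oob.append(float(np.mean(clf.predict(X[test]) != y[test])))
    if not oob:
        return 1.0 - err_resub, 0.0
    err_oob = float(np.mean(oob))
    err_oob_c = min(err_oob, gamma)  # cap at the no-information rate
    if gamma > err_resub:
        R = (err_oob_c - err_resub) / (gamma - err_resub)
    else:
        R = 0.0
    R = float(np.clip(R, 0.0, 1.0))
    w = 0.632 / (1.0 - 0.368 * R)
    err = (1.0 - w) * err_resub + w * err_oob_c
    return 1.0 - err, float(np.std(oob, ddof=0))


def find_inflection(
    k: np.ndarray, accuracy: np.ndarray, window: int = 5, min_gain: float = 0.0025
) -> int:
    """Inflection of the accuracy-versus-k curve.

    The smallest k from which the prospective window-averaged accuracy
    gain — the mean gain per feature over the next ``window`` features of
    the smoothed curve — stays below ``min_gain`` (0.25 percentage
    points); capped at the largest k evaluated. Looking forward rather
    than backward keeps transient plateaus in a still-rising curve from
    triggering a premature stop.
    """
    if len(k) == 1:
        return int(k[0])
    smooth = (
        pd.Series(accuracy).rolling(window, min_periods=1).mean().to_numpy()
    )
    n = len(smooth)
    for i in range(n - 1):
        j = min(i + window, n - 1)
        gain = (smooth[j] - smooth[i]) / (j - i)
        if gain < min_gain:
            return int(k[i])
    return int(k[-1])


def forward_selection(
    ranking: ConsensusRanking,
    matrix,
    labels,
    classifier=None,
    k_max: int | None = None,
    eval_resamples: int = 20,
    seed=None,
    window: int = 5,
    min_gain: float = 0.0025,
) -> SelectionCurve:
    """Accuracy-versus-k curve down the consensus ranking.

    For each k, the classifier (default random forest) is trained on the
    top-k features and its accuracy estimated by the .632 bootstrap with
    out-of-bag evaluation; k* is the inflection point of the curve.
    """
    X = np.asarray(matrix, dtype=float)
    feature_ids = (
        list(matrix.columns) if isinstance(matrix, pd.DataFrame)
        else list(range(X.shape[1]))
    )
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValidationError("labels must contain >= 2 classes")
    if k_max is None:
        k_max = len(ranking.order)
    if k_max > len(ranking.order):
        raise ValidationError("k_max exceeds number of ranked features")
    classifier = classifier or RandomForestClassifier(n_estimators=100, n_jobs=1)
    rng = check_rng(seed)
    col_of = {f: j for j, f in enumerate(feature_ids)}

    ks = np.arange(1, k_max + 1)
    acc = np.empty(len(ks))
    disp = np.empty(len(ks))
    for i, k in enumerate(ks):
        cols = [col_of[f] for f in ranking.order[:k]]
        acc[i], disp[i] = _accuracy_632(
            X[:, cols], y, classifier, eval_resamples, rng
        )
    k_star = find_inflection(ks, acc, window=window, min_gain=min_gain)
    return SelectionCurve(
        k=ks,
        accuracy=acc,
        dispersion=disp,
        k_star=k_star,
        accuracy_at_k_star=float(acc[k_star - 1]),
    )


# ------------------------------------------------------------ orchestrator

@dataclass
class ConsensusResult:
    ranking: ConsensusRanking
    curve: SelectionCurve
    selected: tuple
    comparison: dict  # accuracy with selection vs on all features


def consensus_select(
    matrix,
    labels,
    B: int = 100,
    classifier=None,
    methods: tuple = RANKER_METHODS,
    k_max: int | None = None,
    eval_resamples: int = 20,
    rf_trees: int = 100,
    seed=None,
) -> ConsensusResult:
    """The full protocol: rankers x bootstraps -> Borda -> forward selection.

    Also reports the with/without-selection accuracy comparison (the
    selected subset should discriminate at least as well as the full
    matrix).
    """
    ss_master = np.random.SeedSequence(seed)
    streams = ss_master.spawn(len(methods) + 2)
    lists: list[RankedList] = []
    for method, stream in zip(methods, streams):
        lists.extend(
            bootstrap_rankings(
                matrix, labels, method, B=B,
                seed=np.random.default_rng(stream), rf_trees=rf_trees,
            )
        )
    ranking = borda_aggregate(lists)
    curve = forward_selection(
        ranking, matrix, labels, classifier=classifier, k_max=k_max,
        eval_resamples=eval_resamples,
        seed=np.random.default_rng(streams[len(methods)]),
    )
    selected = tuple(ranking.order[: curve.k_star])

    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    rng_cmp = np.random.default_rng(streams[len(methods) + 1])
    classifier = classifier or RandomForestClassifier(n_estimators=100, n_jobs=1)
    feature_ids = (
        list(matrix.columns) if isinstance(matrix, pd.DataFrame)
        else list(range(X.shape[1]))
    )
    col_of = {f: j for j, f in enumerate(feature_ids)}
    sel_cols = [col_of[f] for f in selected]
    acc_sel, _ = _accuracy_632(X[:, sel_cols], y, classifier, eval_resamples, rng_cmp)
    acc_full, _ = _accuracy_632(X, y, classifier, eval_resamples, rng_cmp)
    return ConsensusResult(
        ranking=ranking,
        curve=curve,
        selected=selected,
        comparison={"accuracy_selected": acc_sel, "accuracy_full": acc_full},
    )


class ConsensusSelector(SelectorMixin, BaseEstimator):
    """sklearn-compatible wrapper around the consensus protocol.

    After ``fit(X, y)`` the fitted attributes are ``ranking_``, ``curve_``,
    ``selected_features_`` and ``support_``; ``transform`` keeps the
    selected columns, so the selector composes with sklearn pipelines.
    """

    def __init__(
        self,
        B: int = 100,
        methods: tuple = RANKER_METHODS,
        classifier=None,
        k_max: int | None = None,
        eval_resamples: int = 20,
        rf_trees: int = 100,
        random_state=None,
    ):
        self.B = B
        self.methods = methods
        self.classifier = classifier
        self.k_max = k_max
        self.eval_resamples = eval_resamples
        self.rf_trees = rf_trees
        self.random_state = random_state

    def fit(self, X, y):
        feature_ids = (
            list(X.columns) if isinstance(X, pd.DataFrame)
            else list(range(np.asarray(X).shape[1]))
        )
        result = consensus_select(
            X, y, B=self.B, classifier=self.classifier, methods=self.methods,
            k_max=self.k_max, eval_resamples=self.eval_resamples,
            rf_trees=self.rf_trees, seed=self.random_state,
        )
        self.ranking_ = result.ranking
        self.curve_ = result.curve
        self.selected_features_ = result.selected
        self.comparison_ = result.comparison
        selected = set(result.selected)
        self.support_ = np.array([f in selected for f in feature_ids])
        self.n_features_in_ = len(feature_ids)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
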