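"""Per-fold feature selection by four simultaneous methods.

For each cross-validation fold, four selections of feature clusters are
produced at (approximately) equal feature cardinality:

* **filter** — clusters whose features pass the univariate Kruskal-Wallis
  test at ``alpha`` (default 0.01); if none pass, the top-n ranking prefix
  whose inner cross-validated accuracy is highest.
* **wrapper** — stepwise inclusion of clusters from a search space of
  top-ranked features, admitting clusters whose addition raises validation
  accuracy (averaged over several fresh balanced splits), with a single
  pruning pass once the selection first exceeds a size trigger.
* **random** — uniformly drawn clusters, a baseline whose performance
  reveals how widespread category differences are.
* **pseudorandom** — uniformly drawn clusters *excluding* anything in the
  filter or wrapper selections, a backup in case those overfit or search
  too narrowly.

All four ride the same fold's ranking and clustering; holdout examples never
influence any selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVC, LinearSVC

from .dataset import (FeatureClusterSet, FoldPlan, RankingResult,
                      balanced_subsample, fresh_training_split)
from .features import FeatureMatrix

__all__ = [
    "WrapperConfig",
    "SelectionResult",
    "filter_select",
    "wrapper_select",
    "random_select",
    "pseudorandom_select",
    "select_for_fold",
    "fit_and_score",
    "CLASSIFIERS",
]

logger = logging.getLogger("featsieve")

#: fallback grid of ranking-prefix lengths tried when no feature passes the
#: filter threshold; capped at the feature count, ties broken toward smaller n
FALLBACK_GRID = (1, 2, 3, 5, 8, 13, 21, 34, 55)


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------

def _make_linear_svm(n_classes: int):
    # liblinear for 2 classes (fast); libsvm one-vs-one beyond that
    if n_classes <= 2:
        return LinearSVC(C=1.0, dual="auto")
    return SVC(kernel="linear", C=1.0)


CLASSIFIERS = {"linear_svm": _make_linear_svm}


try:  # fast path: liblinear without estimator overhead (same solver LinearSVC uses)
    from sklearn.svm._base import _fit_liblinear
except ImportError:  # pragma: no cover
    _fit_liblinear = None


def fit_and_score(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    classifier: str = "linear_svm",
) -> float:
    """Train on standardized features (training-set mean/SD) and return test accuracy."""
    if classifier not in CLASSIFIERS:
        raise ValueError(f"unknown classifier {classifier!r}; available: {sorted(CLASSIFIERS)}")
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd[sd == 0] = 1.0
    Xtr = (X_train - mu) / sd
    Xte = (X_test - mu) / sd
    classes = np.unique(y_train)
    if classifier == "linear_svm" and classes.size == 2 and _fit_liblinear is not None:
        coef, intercept, _ = _fit_liblinear(
            Xtr, y_train, C=1.0, fit_intercept=True, intercept_scaling=1.0,
            class_weight=None, penalty="l2", dual=False, verbose=0,
            max_iter=1000, tol=1e-4, random_state=None, multi_class="ovr",
            loss="squared_hinge", epsilon=0.1, sample_weight=None)
        pred = np.where(Xte @ coef[0] + intercept[0] > 0, classes[1], classes[0])
        return float(np.mean(pred == y_test))
    clf = CLASSIFIERS[classifier](classes.size)
    clf.fit(Xtr, y_train)
    return float(np.mean(clf.predict(Xte) == y_test))


# ---------------------------------------------------------------------------
# Config / result containers
# ---------------------------------------------------------------------------

@dataclass
class WrapperConfig:
    """Stepwise-inclusion parameters.

    The search space holds the ``search_space_factor * target_size``
    top-ranked features; each iteration admits at most
    ``include_fraction * target_size`` features; a single pruning pass runs
    when the selection first exceeds ``prune_trigger * target_size``
    features; performance changes are averaged over ``repeats`` fresh
    balanced splits.
    """

    search_space_factor: float = 2.0
    include_fraction: float = 0.25
    prune_trigger: float = 0.75
    repeats: int = 4
    inner_classifier: str = "linear_svm"

    def __post_init__(self) -> None:
        if self.search_space_factor < 1:
            raise ValueError("search_space_factor must be >= 1")
        if not 0 < self.include_fraction <= 1:
            raise ValueError("include_fraction must be in (0, 1]")
        if not 0 < self.prune_trigger < 1:
            raise ValueError("prune_trigger must be in (0, 1)")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class SelectionResult:
    """The four cluster-id selections for one fold, plus provenance."""

    filter: frozenset[int]
    wrapper: frozenset[int]
    random: frozenset[int]
    pseudorandom: frozenset[int]
    target_size: int  # feature count fixed by the filter selection
    log: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, frozenset[int]]:
        return {"filter": self.filter, "wrapper": self.wrapper,
                "random": self.random, "pseudorandom": self.pseudorandom}


# ---------------------------------------------------------------------------
# Filter
# ---------------------------------------------------------------------------

def filter_select(
    features: FeatureMatrix,
    clusters: FeatureClusterSet,
    ranking: RankingResult,
    plan: FoldPlan,
    fold: int,
    alpha: float = 0.01,
    classifier: str = "linear_svm",
    fallback_ranking: RankingResult | None = None,
) -> set[int]:
    """Top-of-ranking filter selection, sized by the univariate threshold.

    The filter model is always built from the top of the ranking: the number
    of features with Kruskal-Wallis p < alpha in ``ranking`` fixes the
    selection size, and that many features are taken from the top of
    ``fallback_ranking`` (``ranking`` itself if not given), walking cluster
    by cluster.  When the two rankings coincide this is exactly "all
    clusters passing p < alpha", since p is monotone in the ranking.  When
    nothing passes, prefixes of lengths from a fixed grid are scored by
    balanced 5-fold inner cross-validation on the non-holdout data and the
    best (smallest on ties) prefix's clusters are returned, so the selection
    is never empty.
    """
    if features.n_examples == 0 or features.n_features == 0:
        raise ValueError("empty feature matrix")
    order_ranking = fallback_ranking or ranking
    n_pass = int((ranking.p_value < alpha).sum())
    if n_pass:
        cluster_of = clusters.cluster_of()
        sizes = clusters.sizes()
        selected: set[int] = set()
        count = 0
        for f in order_ranking.order:
            cid = int(cluster_of[f])
            if cid in selected:
                continue
            selected.add(cid)
            count += sizes[cid]
            if count >= n_pass:
                break
        return selected

    # fallback: best top-n ranking prefix by inner CV accuracy
    ranking = order_ranking
    pool = plan.non_holdout(fold)
    y = features.labels
    cluster_of = clusters.cluster_of()
    grid = sorted({min(n, features.n_features) for n in FALLBACK_GRID})
    best_n, best_acc = grid[0], -1.0
    inner_rng = np.random.default_rng(plan._rngs[fold].integers(2 ** 31))
    # fixed inner folds shared across the grid for a fair comparison
    inner_folds = _inner_folds(y[pool], 5, inner_rng)
    for n in grid:
        cids = sorted(set(cluster_of[ranking.order[:n]]))
        cols = clusters.features_of(cids)
        accs = []
        for tr_loc, te_loc in inner_folds:
            tr = balanced_subsample(y, pool[tr_loc], inner_rng)
            accs.append(fit_and_score(features.values[np.ix_(tr, cols)], y[tr],
                                      features.values[np.ix_(pool[te_loc], cols)],
                                      y[pool[te_loc]], classifier))
        acc = float(np.mean(accs))
        if acc > best_acc + 1e-12:  # ties -> smaller n (parsimony)
            best_n, best_acc = n, acc
    return set(int(c) for c in set(cluster_of[ranking.order[:best_n]]))


def _inner_folds(y: np.ndarray, k: int, rng: np.random.Generator):
    """Stratified k-fold local indices (round-robin per class after shuffling)."""
    fold_of = np.empty(len(y), dtype=int)
    for c in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == c))
        fold_of[idx] = np.arange(len(idx)) % k
    return [(np.flatnonzero(fold_of != f), np.flatnonzero(fold_of == f))
            for f in range(k)]


# ---------------------------------------------------------------------------
# Wrapper
# ---------------------------------------------------------------------------

def wrapper_select(
    features: FeatureMatrix,
    clusters: FeatureClusterSet,
    ranking: RankingResult,
    plan: FoldPlan,
    fold: int,
    target_size: int,
    cfg: WrapperConfig | None = None,
) -> tuple[set[int], list[dict]]:
    """Stepwise inclusion of clusters until the filter selection's size is matched.

    Each iteration draws ``cfg.repeats`` fresh balanced training/validation
    splits; for each, the change in validation accuracy from adding each
    candidate cluster to the current selection is measured against the
    current selection's accuracy (1/#classes when empty).  Candidates with a
    strictly positive average change are admitted in descending order of
    that change (ties toward higher-ranked clusters) until the per-iteration
    inclusion cap is hit.  When the selection first exceeds the prune
    trigger, clusters are removed one by one (largest first) if removal
    raises accuracy; the same backward-elimination pass runs again after the
    growth loop stops, repeated until no removal helps, so clusters admitted
    on split noise near the end do not survive.  Growth stops at
    ``target_size`` features (the last admitted cluster may overshoot) or
    when no candidate improves; final pruning may leave the selection below
    the target.

    Returns the selected cluster ids and a per-iteration provenance log.
    """
    cfg = cfg or WrapperConfig()
    if target_size <= 0:
        raise ValueError("target_size must be positive")
    y = features.labels
    X = features.values
    n_classes = np.unique(y).size
    cluster_of = clusters.cluster_of()
    sizes = clusters.sizes()

    search_n = int(round(cfg.search_space_factor * target_size))
    search_cids = list(dict.fromkeys(cluster_of[ranking.order[:search_n]]))
    include_cap = max(1, int(round(cfg.include_fraction * target_size)))
    trigger = cfg.prune_trigger * target_size

    selected: list[int] = []
    sel_size = 0
    pruned = False
    log: list[dict] = []

    def _acc(cids: Sequence[int], tr: np.ndarray, va: np.ndarray) -> float:
        if len(cids) == 0:
            return 1.0 / n_classes
        cols = clusters.features_of(cids)
        return fit_and_score(X[np.ix_(tr, cols)], y[tr],
                             X[np.ix_(va, cols)], y[va], cfg.inner_classifier)

    while sel_size < target_size:
        candidates = [c for c in search_cids if c not in selected]
        if not candidates:
            break
        deltas = np.zeros(len(candidates))
        for _ in range(cfg.repeats):
            tr, va = fresh_training_split(plan, fold)
            ref = _acc(selected, tr, va)
            for j, c in enumerate(candidates):
                deltas[j] += _acc(selected + [c], tr, va) - ref
        deltas /= cfg.repeats

        order = np.argsort(-deltas, kind="stable")  # ties -> ranking order
        added, added_feats = [], 0
        for j in order:
            if deltas[j] <= 0:
                break
            if added_feats >= include_cap or sel_size >= target_size:
                break
            c = candidates[j]
            selected.append(c)
            added.append(int(c))
            added_feats += sizes[c]
            sel_size += sizes[c]
        log.append({"added": added, "deltas": {int(candidates[j]): float(deltas[j])
                                               for j in order[:len(candidates)]},
                    "size": sel_size})
        if not added:
            break

        if not pruned and sel_size > trigger:
            pruned = True
            sel_size = _prune_pass(selected, sel_size, sizes, _acc, plan, fold,
                                   cfg.repeats, log)

    # final backward elimination until stable (max 4 passes)
    for _ in range(4):
        before = len(selected)
        sel_size = _prune_pass(selected, sel_size, sizes, _acc, plan, fold,
                               cfg.repeats, log)
        if len(selected) == before:
            break
    return set(int(c) for c in selected), log


def _prune_pass(selected: list[int], sel_size: int, sizes: np.ndarray, _acc,
                plan: FoldPlan, fold: int, repeats: int, log: list[dict]) -> int:
    """One backward-elimination pass: drop clusters whose removal helps.

    Each candidate removal is scored against the full selection on the same
    ``repeats`` fresh balanced splits (paired comparison); every cluster
    whose removal raises average validation accuracy is dropped.
    """
    removed = []
    if len(selected) > 1:
        splits = [fresh_training_split(plan, fold) for _ in range(repeats)]
        ref = sum(_acc(selected, tr, va) for tr, va in splits)
        for c in sorted(selected, key=lambda c: -sizes[c]):
            if len(selected) == 1:
                break
            without = [s for s in selected if s != c]
            if sum(_acc(without, tr, va) for tr, va in splits) > ref:
                selected.remove(c)
                sel_size -= sizes[c]
                removed.append(int(c))
    log.append({"pruned": removed, "size": sel_size})
    return sel_size


# ---------------------------------------------------------------------------
# Random baselines
# ---------------------------------------------------------------------------

def random_select(
    all_clusters: FeatureClusterSet,
    target_size: int,
    rng: np.random.Generator,
) -> set[int]:
    """Uniform cluster draws without replacement until ``target_size`` features."""
    if target_size > all_clusters.n_features:
        raise ValueError(
            f"target_size {target_size} exceeds total feature count "
            f"{all_clusters.n_features}")
    order = rng.permutation(all_clusters.n_clusters)
    sizes = all_clusters.sizes()
    out, total = [], 0
    for c in order:
        out.append(int(c))
        total += sizes[c]
        if total >= target_size:
            break
    return set(out)


def pseudorandom_select(
    all_clusters: FeatureClusterSet,
    excluded: set[int],
    target_size: int,
    rng: np.random.Generator,
) -> set[int]:
    """Uniform cluster draws restricted to clusters outside ``excluded``.

    When the residual pool holds fewer than ``target_size`` features the
    selection shrinks to the pool with a logged warning.
    """
    pool = [c for c in range(all_clusters.n_clusters) if c not in excluded]
    sizes = all_clusters.sizes()
    pool_feats = int(sizes[pool].sum()) if pool else 0
    if pool_feats < target_size:
        logger.warning(
            "pseudorandom pool has only %d features (< target %d); shrinking",
            pool_feats, target_size)
        return set(pool)
    order = rng.permutation(len(pool))
    out, total = [], 0
    for i in order:
        c = pool[i]
        out.append(int(c))
        total += sizes[c]
        if total >= target_size:
            break
    return set(out)


# ---------------------------------------------------------------------------
# Per-fold driver
# ---------------------------------------------------------------------------

def select_for_fold(
    features: FeatureMatrix,
    clusters: FeatureClusterSet,
    filter_ranking: RankingResult,
    search_ranking: RankingResult,
    plan: FoldPlan,
    fold: int,
    alpha: float = 0.01,
    wrapper_cfg: WrapperConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SelectionResult:
    """Run all four selection methods for one fold.

    ``filter_ranking`` carries the p-values judged against ``alpha`` (scored
    on a balanced training split, like every other feature-selecting step);
    ``search_ranking`` orders the wrapper's search space and the fallback
    prefix (scored on the full non-holdout data, the most stable ranking
    available without touching the holdout).
    """
    rng = rng or np.random.default_rng()
    filt = filter_select(features, clusters, filter_ranking, plan, fold,
                         alpha=alpha, fallback_ranking=search_ranking,
                         classifier=(wrapper_cfg or WrapperConfig()).inner_classifier)
    target = int(clusters.sizes()[list(filt)].sum())
    wrap, wlog = wrapper_select(features, clusters, search_ranking, plan, fold,
                                target, wrapper_cfg)
    rand = random_select(clusters, target, rng)
    pseudo = pseudorandom_select(clusters, filt | wrap, target, rng)
    return SelectionResult(frozenset(filt), frozenset(wrap), frozenset(rand),
                           frozenset(pseudo), target,
                           {"wrapper_log": wlog, "fold": fold})
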