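"""Cross-validation plans, univariate feature ranking, correlated-feature clustering.

The selection pipeline runs inside k-fold cross-validation: per fold, one
subset of examples is held out and touched only when the final models are
scored.  Within the remaining examples, every step that selects a feature
draws a *fresh* pseudo-random split into a class-balanced training set and a
validation set, which reduces overfitting of the selection to any one split.

Features are ranked univariately with the Kruskal-Wallis rank test (its H
statistic is the "chi-square score" used throughout), and features that
share at least ``r2_threshold`` of their variance with a higher-ranking seed
feature are clustered so that correlated features are always selected
together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .features import FeatureMatrix

__all__ = [
    "CVConfig",
    "FoldPlan",
    "RankingResult",
    "FeatureClusterSet",
    "make_fold_plan",
    "fresh_training_split",
    "rank_features",
    "cluster_correlated",
]


@dataclass
class CVConfig:
    k: int = 10
    train_fraction: float = 0.5
    small_data_mode: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class FoldPlan:
    """Holdout assignment plus per-fold generators of balanced training splits.

    In standard mode the k holdout sets are disjoint and cover all examples
    (stratified: each class is shuffled and dealt round-robin across folds).
    In small-data mode each fold is an independent 50/50 train/holdout
    partition instead, trading holdout independence for holdout size.
    """

    labels: np.ndarray
    holdout_sets: list[np.ndarray]
    train_fraction: float
    small_data_mode: bool = False
    _rngs: list[np.random.Generator] = field(default_factory=list, repr=False)

    @property
    def k(self) -> int:
        return len(self.holdout_sets)

    def non_holdout(self, fold: int) -> np.ndarray:
        mask = np.ones(len(self.labels), dtype=bool)
        mask[self.holdout_sets[fold]] = False
        return np.flatnonzero(mask)


def make_fold_plan(features: FeatureMatrix, cfg: CVConfig) -> FoldPlan:
    """Build a stratified k-fold plan (or k 50/50 partitions in small-data mode)."""
    labels = features.labels
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.k + 1)
    assign_rng = np.random.default_rng(children[0])
    fold_rngs = [np.random.default_rng(c) for c in children[1:]]

    classes, counts = np.unique(labels, return_counts=True)
    if cfg.small_data_mode:
        holdouts = []
        for _ in range(cfg.k):
            ho = []
            for c in classes:
                idx = assign_rng.permutation(np.flatnonzero(labels == c))
                ho.append(idx[: len(idx) // 2])
            holdouts.append(np.sort(np.concatenate(ho)))
        return FoldPlan(labels, holdouts, cfg.train_fraction, True, fold_rngs)

    if counts.min() < cfg.k:
        raise ValueError(
            f"class {classes[counts.argmin()]} has {counts.min()} examples, fewer than "
            f"k={cfg.k}; use small_data_mode=True (50/50 train/holdout partitions) "
            "or reduce k"
        )
    fold_of = np.empty(len(labels), dtype=int)
    for c in classes:
        idx = assign_rng.permutation(np.flatnonzero(labels == c))
        fold_of[idx] = np.arange(len(idx)) % cfg.k  # round-robin after shuffling
    holdouts = [np.flatnonzero(fold_of == f) for f in range(cfg.k)]
    return FoldPlan(labels, holdouts, cfg.train_fraction, False, fold_rngs)


def fresh_training_split(plan: FoldPlan, fold: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw a new balanced (training, validation) split of a fold's non-holdout data.

    Each call re-randomizes: per class, ``floor(train_fraction * min_class_count)``
    examples are sampled without replacement into training (so training always
    holds equal per-class counts); everything else falls to validation.
    """
    if not 0 <= fold < plan.k:
        raise IndexError(f"fold {fold} out of range for k={plan.k}")
    rng = plan._rngs[fold]
    pool = plan.non_holdout(fold)
    labs = plan.labels[pool]
    classes, counts = np.unique(labs, return_counts=True)
    n_per_class = max(1, int(plan.train_fraction * counts.min()))
    train = []
    for c in classes:
        idx = pool[labs == c]
        train.append(rng.choice(idx, size=n_per_class, replace=False))
    train = np.sort(np.concatenate(train))
    val = np.setdiff1d(pool, train, assume_unique=True)
    return train, val


def balanced_subsample(labels: np.ndarray, pool: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Sample min-class-count examples per class from ``pool`` (for unbiased training)."""
    labs = labels[pool]
    classes, counts = np.unique(labs, return_counts=True)
    m = counts.min()
    out = [rng.choice(pool[labs == c], size=m, replace=False) for c in classes]
    return np.sort(np.concatenate(out))


# ---------------------------------------------------------------------------
# Univariate ranking
# ---------------------------------------------------------------------------

@dataclass
class RankingResult:
    statistic: np.ndarray  # Kruskal-Wallis H per feature
    p_value: np.ndarray
    order: np.ndarray  # feature indices by descending H (ties: lower index first)


def rank_features(features: FeatureMatrix, subset: Sequence[int] | None = None) -> RankingResult:
    """Kruskal-Wallis H ("chi-square score") and p per feature on a subset.

    Vectorized over features with mid-rank tie correction; a constant feature
    gets H = 0, p = 1.  Cross-checked against ``scipy.stats.kruskal`` in the
    test suite.
    """
    idx = np.arange(features.n_examples) if subset is None else np.asarray(subset)
    X = features.values[idx]
    y = features.labels[idx]
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("ranking requires at least 2 classes in the subset")
    N = X.shape[0]

    ranks = stats.rankdata(X, axis=0)  # mid-ranks
    sum_term = np.zeros(X.shape[1])
    for c in classes:
        m = y == c
        R = ranks[m].sum(axis=0)
        sum_term += R * R / m.sum()
    H = 12.0 / (N * (N + 1)) * sum_term - 3.0 * (N + 1)

    # mid-rank tie correction: 1 - sum(t^3 - t) / (N^3 - N), per feature
    Xs = np.sort(X, axis=0)
    new = np.ones_like(Xs, dtype=bool)
    new[1:] = Xs[1:] != Xs[:-1]
    tie_sum = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        bnd = np.flatnonzero(new[:, j])
        t = np.diff(np.append(bnd, N))
        tie_sum[j] = np.sum(t ** 3 - t)
    corr = 1.0 - tie_sum / (N ** 3 - N)
    with np.errstate(divide="ignore", invalid="ignore"):
        H = np.where(corr > 0, H / corr, 0.0)
    H = np.maximum(H, 0.0)  # guard tiny negative rounding

    p = np.where(H > 0, stats.chi2.sf(H, df=classes.size - 1), 1.0)
    order = np.argsort(-H, kind="stable")
    return RankingResult(H, p, order)


# ---------------------------------------------------------------------------
# Correlated-feature clustering
# ---------------------------------------------------------------------------

@dataclass
class FeatureClusterSet:
    """A partition of features into clusters of shared-variance groups.

    ``clusters[i]`` holds the member feature indices of cluster id ``i``;
    clusters are ordered by the rank of their seed feature.
    """

    clusters: list[np.ndarray]
    r2_threshold: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_features(self) -> int:
        return sum(len(c) for c in self.clusters)

    def sizes(self) -> np.ndarray:
        return np.array([len(c) for c in self.clusters])

    def features_of(self, cluster_ids: Sequence[int]) -> np.ndarray:
        """All member feature indices of the given cluster ids, sorted."""
        if len(cluster_ids) == 0:
            return np.array([], dtype=int)
        return np.sort(np.concatenate([self.clusters[i] for i in cluster_ids]))

    def cluster_of(self) -> np.ndarray:
        """Inverse map: feature index -> cluster id."""
        out = np.empty(self.n_features, dtype=int)
        for cid, members in enumerate(self.clusters):
            out[members] = cid
        return out


def cluster_correlated(
    features: FeatureMatrix,
    ranking: RankingResult,
    subset: Sequence[int] | None = None,
    r2_threshold: float = 0.25,
) -> FeatureClusterSet:
    """Greedy seeded clustering of features sharing variance with a seed.

    Walking the ranking top-down, each still-unassigned feature seeds a
    cluster and absorbs every unassigned feature whose squared Pearson
    correlation with the *seed* reaches ``r2_threshold`` (membership is
    judged against the seed, not all members).  Link groups are absorbed
    atomically: pulling one member of a linked pair pulls the rest.
    """
    idx = np.arange(features.n_examples) if subset is None else np.asarray(subset)
    X = features.values[idx].astype(float)
    # standardize; zero-variance features correlate with nothing
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    nz = sd > 0
    Z = np.zeros_like(X)
    Z[:, nz] = (X[:, nz] - mu[nz]) / sd[nz]
    n = X.shape[0]

    link = features.link_groups
    assigned = np.zeros(features.n_features, dtype=bool)
    clusters: list[np.ndarray] = []
    for seed in ranking.order:
        if assigned[seed]:
            continue
        r = Z.T @ Z[:, seed] / n
        members = np.flatnonzero(~assigned & (r * r >= r2_threshold))
        members = set(members.tolist()) | {int(seed)}
        # absorb link groups atomically (closure over linked partners)
        grp_ids = {link[m] for m in members}
        members |= set(np.flatnonzero(np.isin(link, list(grp_ids)) & ~assigned).tolist())
        members = np.array(sorted(members), dtype=int)
        assigned[members] = True
        clusters.append(members)
    return FeatureClusterSet(clusters, r2_threshold)
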