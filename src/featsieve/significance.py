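"""Model evaluation, permutation null, and method/feature significance.

The four selections of each fold (filter, wrapper, random, pseudorandom)
plus a full model are trained on all balanced non-holdout data and scored on
the holdout examples.  A permutation null of chance accuracies is built by
retraining each (fold, method) model ``shuffles`` times with shuffled
training labels (k x shuffles x 4 values at defaults).  Method-level
significance is a permutation tail probability of the fold-mean accuracy.

Feature-level significance works on a different level: a feature is a
candidate when it appears in a model scoring above the null's 99th
percentile, and is flagged as *relevant* when its mean associated holdout
accuracy over all models containing it exceeds the maximum of a control
distribution corrected for regression to the mean — a feature used m times
is compared against maxima of means of m null draws, so rarely-used
features face a more conservative criterion.  This two-level design lets
individual features reach significance even when every selection method's
overall performance does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import (CVConfig, FeatureClusterSet, FoldPlan, balanced_subsample,
                      cluster_correlated, fresh_training_split, make_fold_plan,
                      rank_features)
from .features import FeatureMatrix
from .selection import (SelectionResult, WrapperConfig, fit_and_score,
                        select_for_fold)

__all__ = [
    "PermutationConfig",
    "SignificanceResult",
    "evaluate_selections",
    "build_null_distribution",
    "method_significance",
    "tally_feature_stats",
    "control_criterion",
    "feature_significance",
    "find_feature_combinations",
    "run_pipeline",
]

METHODS = ("filter", "wrapper", "random", "pseudorandom")
ALL_MODELS = METHODS + ("full",)


@dataclass
class PermutationConfig:
    shuffles_per_fold_per_method: int = 25
    percentile: float = 99.0
    classifier: str = "linear_svm"

    def __post_init__(self) -> None:
        if self.shuffles_per_fold_per_method < 1:
            raise ValueError("shuffles_per_fold_per_method must be >= 1")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0, 100)")


@dataclass
class SignificanceResult:
    """Everything the significance stage computes for one run."""

    method_performance: pd.DataFrame  # folds x (filter, wrapper, random, pseudorandom, full)
    null_distribution: np.ndarray  # shape (k, 4, shuffles)
    method_p: dict[str, float]
    feature_stats: pd.DataFrame  # usage, mean_perf, max_perf, criterion, flagged
    relevant_features: np.ndarray  # flagged feature indices
    selections: list[SelectionResult] = field(default_factory=list)
    clusters: list[FeatureClusterSet] = field(default_factory=list)
    feature_meta: pd.DataFrame | None = None
    sources: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    @property
    def null_flat(self) -> np.ndarray:
        return self.null_distribution.ravel()


# ---------------------------------------------------------------------------
# Evaluation and permutation null
# ---------------------------------------------------------------------------

def _feature_sets(selections: Sequence[SelectionResult],
                  clusters: Sequence[FeatureClusterSet]) -> list[dict[str, np.ndarray]]:
    """Per fold, the member feature indices of each method's selection."""
    out = []
    for sel, clu in zip(selections, clusters):
        out.append({m: clu.features_of(sorted(ids))
                    for m, ids in sel.as_dict().items()})
    return out


def evaluate_selections(
    features: FeatureMatrix,
    selections: Sequence[SelectionResult],
    clusters: Sequence[FeatureClusterSet],
    plan: FoldPlan,
    classifier: str = "linear_svm",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Holdout accuracy per fold for the four selections plus the full model.

    Training uses all of the fold's non-holdout data, balanced to equal
    per-class counts; the full model (all features) is always evaluated as a
    reference.
    """
    rng = rng or np.random.default_rng()
    fsets = _feature_sets(selections, clusters)
    rows = np.empty((plan.k, len(ALL_MODELS)))
    y = features.labels
    for fold in range(plan.k):
        train = balanced_subsample(y, plan.non_holdout(fold), rng)
        ho = plan.holdout_sets[fold]
        for j, method in enumerate(ALL_MODELS):
            cols = (np.arange(features.n_features) if method == "full"
                    else fsets[fold][method])
            rows[fold, j] = fit_and_score(
                features.values[np.ix_(train, cols)], y[train],
                features.values[np.ix_(ho, cols)], y[ho], classifier)
    return pd.DataFrame(rows, columns=ALL_MODELS,
                        index=pd.RangeIndex(plan.k, name="fold"))


def build_null_distribution(
    features: FeatureMatrix,
    selections: Sequence[SelectionResult],
    clusters: Sequence[FeatureClusterSet],
    plan: FoldPlan,
    cfg: PermutationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Chance accuracies: per fold and method, models trained on shuffled labels.

    Returns an array of shape (k, 4, shuffles); flattened it holds
    k x shuffles x 4 values (1000 at defaults).  Labels are shuffled within
    the balanced training data only; holdout labels stay intact.
    """
    cfg = cfg or PermutationConfig()
    rng = rng or np.random.default_rng()
    fsets = _feature_sets(selections, clusters)
    y = features.labels
    null = np.empty((plan.k, len(METHODS), cfg.shuffles_per_fold_per_method))
    for fold in range(plan.k):
        train = balanced_subsample(y, plan.non_holdout(fold), rng)
        ho = plan.holdout_sets[fold]
        for j, method in enumerate(METHODS):
            cols = fsets[fold][method]
            Xtr = features.values[np.ix_(train, cols)]
            Xho = features.values[np.ix_(ho, cols)]
            for s in range(cfg.shuffles_per_fold_per_method):
                null[fold, j, s] = fit_and_score(
                    Xtr, rng.permutation(y[train]), Xho, y[ho], cfg.classifier)
    return null


def method_significance(
    method_performance: pd.DataFrame,
    null_distribution: np.ndarray,
) -> dict[str, float]:
    """Permutation tail probability of each method's fold-mean accuracy.

    p = (#null >= observed + 1) / (#null + 1); the +1 smoothing avoids zero
    p-values from a finite permutation sample.
    """
    null = np.ravel(null_distribution)
    B = null.size
    out = {}
    for m in METHODS:
        obs = method_performance[m].mean()
        out[m] = (np.sum(null >= obs) + 1.0) / (B + 1.0)
    return out


# ---------------------------------------------------------------------------
# Feature-level significance
# ---------------------------------------------------------------------------

#: methods whose models credit the features they contain.  The random and
#: pseudorandom baselines are excluded: they do not *choose* features, and on
#: easy problems their models score well above chance, which would flag every
#: feature that happened to ride one lucky random draw.
TALLY_METHODS = ("filter", "wrapper")


def tally_feature_stats(
    n_features: int,
    method_performance: pd.DataFrame,
    selections: Sequence[SelectionResult],
    clusters: Sequence[FeatureClusterSet],
    methods: Sequence[str] = TALLY_METHODS,
) -> pd.DataFrame:
    """Usage count, mean and max associated holdout accuracy per feature.

    Tallied over the evaluated filter and wrapper selections across folds;
    the full model and the random baselines are excluded, since features are
    credited only for selections that deliberately chose them.
    """
    fsets = _feature_sets(selections, clusters)
    usage = np.zeros(n_features, dtype=int)
    total = np.zeros(n_features)
    best = np.full(n_features, -np.inf)
    for fold, fs in enumerate(fsets):
        for method in methods:
            acc = method_performance.loc[fold, method]
            cols = fs[method]
            usage[cols] += 1
            total[cols] += acc
            np.maximum.at(best, cols, acc)
    with np.errstate(invalid="ignore"):
        mean = np.where(usage > 0, total / np.maximum(usage, 1), np.nan)
    best[usage == 0] = np.nan
    return pd.DataFrame({"usage": usage, "mean_perf": mean, "max_perf": best})


def control_criterion(null_distribution: np.ndarray, m: int) -> float:
    """Relevance criterion for a feature used ``m`` times.

    The control distribution holds one average of m values per entry of the
    permutation null, taken as sliding windows over the sorted null, so its
    maximum is the mean of the m largest chance accuracies.  For m = 1 this
    is exactly the null maximum; it contracts slowly toward the bulk as m
    grows, so rarely-used features face the more conservative criterion.
    (An i.i.d.-resampled control would shrink like 1/sqrt(m) and quickly
    fall below the accuracy of any model that beats chance at all, flagging
    every feature such a model ever touched.)
    """
    null = np.sort(np.ravel(null_distribution))
    m = max(1, min(int(m), null.size))
    return float(null[-m:].mean())


def feature_significance(
    feature_stats: pd.DataFrame,
    null_distribution: np.ndarray,
    cfg: PermutationConfig | None = None,
) -> pd.DataFrame:
    """Flag relevant features against regression-to-the-mean-corrected controls.

    Candidates are features that appeared in at least one model scoring
    above the null's ``percentile`` (99th by default, compensating for
    testing multiple selection methods).  A candidate used m times is
    flagged when its mean associated accuracy exceeds the maximum of the
    m-average control distribution (see :func:`control_criterion`); for
    m = 1 that maximum is the null maximum itself.

    Returns ``feature_stats`` with added ``criterion`` and ``flagged``
    columns.
    """
    cfg = cfg or PermutationConfig()
    null = np.ravel(null_distribution)
    thresh = np.percentile(null, cfg.percentile)

    out = feature_stats.copy()
    out["criterion"] = np.nan
    out["flagged"] = False
    candidates = out.index[(out["usage"] > 0) & (out["max_perf"] > thresh)]
    crit_for_m: dict[int, float] = {}
    for feat in candidates:
        m = int(out.at[feat, "usage"])
        if m not in crit_for_m:
            crit_for_m[m] = control_criterion(null, m)
        out.at[feat, "criterion"] = crit_for_m[m]
        out.at[feat, "flagged"] = bool(out.at[feat, "mean_perf"] > crit_for_m[m])
    return out


def find_feature_combinations(
    features: FeatureMatrix,
    relevant_features: Sequence[int],
    plan: FoldPlan,
    classifier: str = "linear_svm",
    rng: np.random.Generator | None = None,
    max_features: int = 40,
) -> pd.DataFrame:
    """Search pairs of relevant features whose joint accuracy stands out.

    For every unordered pair, cross-validated accuracy with both features is
    compared with the first feature alone; pairs whose combined accuracy
    exceeds the mean + 2 SD of all tested combined accuracies are flagged.
    With more than ``max_features`` relevant features, only the strongest
    (by single-feature accuracy) are paired, keeping the quadratic search
    tractable.
    """
    rng = rng or np.random.default_rng()
    rel = list(dict.fromkeys(int(f) for f in relevant_features))
    if len(rel) < 2:
        return pd.DataFrame(columns=["feature_a", "feature_b", "acc_pair",
                                     "acc_single", "flagged"])
    y = features.labels
    trains = [balanced_subsample(y, plan.non_holdout(f), rng) for f in range(plan.k)]

    def cv_acc(cols: list[int]) -> float:
        accs = [fit_and_score(features.values[np.ix_(tr, cols)], y[tr],
                              features.values[np.ix_(plan.holdout_sets[f], cols)],
                              y[plan.holdout_sets[f]], classifier)
                for f, tr in enumerate(trains)]
        return float(np.mean(accs))

    singles = {f: cv_acc([f]) for f in rel}
    if len(rel) > max_features:
        rel = sorted(rel, key=lambda f: -singles[f])[:max_features]
    rows = [(a, b, cv_acc([a, b]), singles[a]) for a, b in combinations(rel, 2)]
    df = pd.DataFrame(rows, columns=["feature_a", "feature_b", "acc_pair", "acc_single"])
    cut = df["acc_pair"].mean() + 2 * df["acc_pair"].std(ddof=0)
    df["flagged"] = df["acc_pair"] > cut
    return df


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    features: FeatureMatrix,
    cv: CVConfig | None = None,
    wrapper_cfg: WrapperConfig | None = None,
    perm_cfg: PermutationConfig | None = None,
    alpha: float = 0.01,
    r2_threshold: float = 0.25,
    seed: int | None = None,
) -> SignificanceResult:
    """Full selection-and-significance run on a feature matrix.

    Per fold: rank features (Kruskal-Wallis on non-holdout data), cluster
    correlated features, produce the four selections; then evaluate all
    models on holdout data, build the permutation null, and flag relevant
    features.  All randomness derives from ``seed`` (the CV config's own
    seed, when set, governs the fold plan).
    """
    cv = cv or CVConfig()
    wrapper_cfg = wrapper_cfg or WrapperConfig()
    perm_cfg = perm_cfg or PermutationConfig()
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(3)
    if cv.seed is None:
        cv = CVConfig(cv.k, cv.train_fraction, cv.small_data_mode,
                      int(np.random.default_rng(kids[0]).integers(2 ** 31)))
    sel_rng = np.random.default_rng(kids[1])
    eval_rng = np.random.default_rng(kids[2])

    plan = make_fold_plan(features, cv)
    selections, cluster_sets = [], []
    for fold in range(plan.k):
        # the filter's p-value test is a feature-selecting step and so runs
        # on a fresh balanced training split; clustering and the wrapper's
        # search-space ranking use the full non-holdout data (the most
        # stable estimates available without touching the holdout)
        nonho = plan.non_holdout(fold)
        stable_ranking = rank_features(features, nonho)
        clusters = cluster_correlated(features, stable_ranking, nonho, r2_threshold)
        split, _ = fresh_training_split(plan, fold)
        filter_ranking = rank_features(features, split)
        selections.append(select_for_fold(features, clusters, filter_ranking,
                                          stable_ranking, plan, fold,
                                          alpha=alpha, wrapper_cfg=wrapper_cfg,
                                          rng=sel_rng))
        cluster_sets.append(clusters)

    perf = evaluate_selections(features, selections, cluster_sets, plan,
                               perm_cfg.classifier, eval_rng)
    null = build_null_distribution(features, selections, cluster_sets, plan,
                                   perm_cfg, eval_rng)
    method_p = method_significance(perf, null)
    stats = tally_feature_stats(features.n_features, perf, selections, cluster_sets)
    stats = feature_significance(stats, null, perm_cfg)
    relevant = stats.index[stats["flagged"]].to_numpy()

    return SignificanceResult(
        method_performance=perf,
        null_distribution=null,
        method_p=method_p,
        feature_stats=stats,
        relevant_features=relevant,
        selections=selections,
        clusters=cluster_sets,
        feature_meta=features.feature_meta,
        sources=list(features.sources),
        config={
            "k": cv.k, "train_fraction": cv.train_fraction,
            "small_data_mode": cv.small_data_mode,
            "alpha": alpha, "r2_threshold": r2_threshold,
            "classifier": perm_cfg.classifier,
            "shuffles": perm_cfg.shuffles_per_fold_per_method,
            "percentile": perm_cfg.percentile,
            "wrapper": {"search_space_factor": wrapper_cfg.search_space_factor,
                        "include_fraction": wrapper_cfg.include_fraction,
                        "prune_trigger": wrapper_cfg.prune_trigger,
                        "repeats": wrapper_cfg.repeats},
            "seed": seed,
        },
    )
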