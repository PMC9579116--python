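"""Synthetic benchmark: mock data with known relevant features, plus baselines.

The generator builds a two-class feature matrix with an *exact whole-set
null*: per feature, one multiset of standard-normal values is drawn and
assigned to both classes in independently shuffled example order, so no
feature differs between the classes as a whole (differences can still arise
inside cross-validation splits).  A randomly chosen subset of features is
then manipulated by shifting every class-1 value upward, with shift sizes
linearly spaced from 0.5 down to 0.25 standard deviations across the
manipulated features — a gradient from easy to hard.

Because the ground truth is known, selectors can be scored by hits
(manipulated features flagged) and false alarms (unmanipulated features
flagged).  A per-fold two-sample t-test selector at several uncorrected
alpha levels serves as the baseline comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import CVConfig, FoldPlan, fresh_training_split, make_fold_plan
from .features import FeatureMatrix, ImageSet
from .selection import WrapperConfig
from .significance import PermutationConfig, run_pipeline

__all__ = [
    "MockDataSpec",
    "BenchmarkResult",
    "generate_mock_dataset",
    "ttest_select",
    "ttest_detections",
    "run_benchmark",
    "generate_localized_image_set",
    "TTEST_ALPHAS",
    "TTEST_RULES",
]

TTEST_ALPHAS = (0.05, 0.01, 0.001)


@dataclass
class MockDataSpec:
    """Parameters of the mock-data simulator.

    Defaults follow the validation study: 400 features, 250 examples per
    class, effect sizes from 0.5 down to 0.25 SD over the manipulated
    features, 30 iterations per condition.
    """

    n_features: int = 400
    n_per_class: int = 250
    n_relevant: int = 25
    effect_high: float = 0.5
    effect_low: float = 0.25
    n_iterations: int = 30
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_relevant > self.n_features:
            raise ValueError("n_relevant cannot exceed n_features")


def generate_mock_dataset(
    spec: MockDataSpec,
    rng: np.random.Generator | int | None = None,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Generate one mock dataset and return it with the manipulated indices.

    Both classes receive the identical value multiset per feature (shuffled
    independently), then ``n_relevant`` randomly chosen features get a
    per-feature shift added to all class-1 values, linearly spaced from
    ``effect_high`` down to ``effect_low`` SD units.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n, f = spec.n_per_class, spec.n_features
    base = rng.standard_normal((n, f))
    class1 = rng.permuted(base, axis=0)
    class2 = rng.permuted(base, axis=0)
    relevant = np.sort(rng.choice(f, size=spec.n_relevant, replace=False))
    if spec.n_relevant:
        deltas = np.linspace(spec.effect_high, spec.effect_low, spec.n_relevant)
        class1[:, relevant] += deltas
    values = np.vstack([class1, class2])
    labels = np.repeat([1, 2], n)
    meta = pd.DataFrame({"space": "mock", "layer": 0,
                         "c0": np.arange(f, dtype=float),
                         "c1": np.nan, "c2": np.nan})
    fm = FeatureMatrix(values, labels, meta, np.arange(f))
    return fm, relevant


# ---------------------------------------------------------------------------
# t-test baseline
# ---------------------------------------------------------------------------

#: per-fold aggregation rules for the t-test selector
TTEST_RULES = ("majority", "any", "all", "whole", "single")


def ttest_detections(
    features: FeatureMatrix,
    plan: FoldPlan,
    alphas: Sequence[float],
    rule: str = "majority",
    equal_var: bool = True,
) -> dict[float, np.ndarray]:
    """t-test detected sets for several alpha levels on shared per-fold splits.

    All alphas are judged from the same p-values per fold, so the detected
    sets nest: stricter alphas always detect a subset.
    """
    if rule not in TTEST_RULES:
        raise ValueError(f"unknown aggregation rule {rule!r}; one of {TTEST_RULES}")
    y = features.labels
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("the t-test selector requires exactly 2 classes")

    def pvals(idx: np.ndarray) -> np.ndarray:
        a = features.values[idx][y[idx] == classes[0]]
        b = features.values[idx][y[idx] == classes[1]]
        t = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
        return np.nan_to_num(t.pvalue, nan=1.0)

    if rule == "whole":
        p = pvals(np.arange(features.n_examples))
        return {a: np.flatnonzero(p < a) for a in alphas}
    if rule == "single":
        train, _ = fresh_training_split(plan, 0)
        p = pvals(train)
        return {a: np.flatnonzero(p < a) for a in alphas}

    hits = {a: np.zeros(features.n_features, dtype=int) for a in alphas}
    for fold in range(plan.k):
        train, _ = fresh_training_split(plan, fold)
        p = pvals(train)
        for a in alphas:
            hits[a] += p < a
    if rule == "majority":
        return {a: np.flatnonzero(h > plan.k / 2) for a, h in hits.items()}
    if rule == "any":
        return {a: np.flatnonzero(h >= 1) for a, h in hits.items()}
    return {a: np.flatnonzero(h == plan.k) for a, h in hits.items()}  # all


def ttest_select(
    features: FeatureMatrix,
    plan: FoldPlan,
    alpha: float,
    rule: str = "majority",
    equal_var: bool = True,
) -> np.ndarray:
    """Two-sample t-test selector on the same folding as the main pipeline.

    Per fold, every feature is tested on a fresh balanced training split of
    the fold's non-holdout data.  How per-fold results aggregate into one
    detected set is set by ``rule``:

    * ``majority`` (default) — significant in a strict majority of folds;
    * ``any`` / ``all`` — significant in at least one / every fold;
    * ``whole`` — a single test on the whole dataset, ignoring folds;
    * ``single`` — a single test on one balanced training split.
    """
    return ttest_detections(features, plan, (alpha,), rule, equal_var)[alpha]


# ---------------------------------------------------------------------------
# Benchmark
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkResult:
    """Hits/false-alarm accounting per method and condition."""

    per_iteration: pd.DataFrame  # condition, iteration, method, hits, false_alarms
    summary: pd.DataFrame  # mean hits / FA per (condition, method)
    overall: pd.DataFrame  # per method: mean and SD of percent found

    def to_csv(self, path) -> None:
        self.per_iteration.to_csv(path, index=False)


def _summarize(per_iter: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    summary = (per_iter.groupby(["condition", "method"], sort=False)
               [["hits", "false_alarms"]].mean().reset_index())
    pct = per_iter.assign(pct=100.0 * per_iter["hits"] / per_iter["condition"])
    overall = (pct.groupby("method", sort=False)["pct"]
               .agg(mean_pct="mean", sd_pct=lambda s: s.std(ddof=1))
               .reset_index())
    return summary, overall


def run_benchmark(
    spec: MockDataSpec | None = None,
    n_relevant_grid: Sequence[int] = (25, 50, 100),
    methods: Sequence[str] = ("pipeline", "ttest_05", "ttest_01", "ttest_001"),
    cv: CVConfig | None = None,
    wrapper_cfg: WrapperConfig | None = None,
    perm_cfg: PermutationConfig | None = None,
    ttest_rule: str = "majority",
    seed: int | None = None,
    progress: bool = False,
) -> BenchmarkResult:
    """Score the pipeline and t-test baselines on fresh mock data.

    Per condition (number of manipulated features) and iteration, a new mock
    dataset is generated; all methods run on the same data and the same fold
    plan.  Pipeline hits are the flagged relevant features; false alarms are
    flagged unmanipulated features.  ``methods`` may name ``pipeline`` and/or
    ``ttest_05``/``ttest_01``/``ttest_001``.
    """
    spec = spec or MockDataSpec()
    cv = cv or CVConfig()
    root = np.random.SeedSequence(seed)
    rows = []
    for cond in n_relevant_grid:
        cond_spec = replace(spec, n_relevant=cond)
        for it in range(spec.n_iterations):
            it_ss = root.spawn(1)[0]
            kids = it_ss.spawn(3)
            fm, relevant = generate_mock_dataset(cond_spec, np.random.default_rng(kids[0]))
            rel = set(relevant.tolist())
            plan_seed = int(np.random.default_rng(kids[1]).integers(2 ** 31))
            it_cv = CVConfig(cv.k, cv.train_fraction, cv.small_data_mode, plan_seed)
            ttest_methods = [m for m in methods if m.startswith("ttest_")]
            ttest_sets = {}
            if ttest_methods:
                alphas = [float("0." + m.split("_")[1]) for m in ttest_methods]
                plan = make_fold_plan(fm, it_cv)
                dets = ttest_detections(fm, plan, alphas, rule=ttest_rule)
                ttest_sets = {m: set(dets[a].tolist())
                              for m, a in zip(ttest_methods, alphas)}
            for method in methods:
                if method == "pipeline":
                    res = run_pipeline(fm, cv=it_cv, wrapper_cfg=wrapper_cfg,
                                       perm_cfg=perm_cfg,
                                       seed=int(np.random.default_rng(kids[2]).integers(2 ** 31)))
                    flagged = set(res.relevant_features.tolist())
                elif method in ttest_sets:
                    flagged = ttest_sets[method]
                else:
                    raise ValueError(f"unknown benchmark method {method!r}")
                rows.append({"condition": cond, "iteration": it, "method": method,
                             "hits": len(flagged & rel),
                             "false_alarms": len(flagged - rel)})
            if progress:
                print(f"condition {cond}, iteration {it + 1}/{spec.n_iterations} done",
                      flush=True)
    per_iter = pd.DataFrame(rows)
    summary, overall = _summarize(per_iter)
    return BenchmarkResult(per_iter, summary, overall)


# ---------------------------------------------------------------------------
# Synthetic image set with a localized category difference
# ---------------------------------------------------------------------------

def generate_localized_image_set(
    n_per_class: int = 60,
    size: int = 60,
    region: tuple[int, int, int, int] = (32, 44, 18, 42),
    contrast: float = 0.6,
    jitter: int = 2,
    rng: np.random.Generator | int | None = None,
) -> tuple[ImageSet, tuple[int, int, int, int]]:
    """Synthetic two-category image set differing only in a localized region.

    A stand-in for face photographs with open versus closed mouths: both
    categories share the same smooth-noise background statistics; category 2
    additionally carries a dark horizontal bar inside ``region``
    (row_start, row_stop, col_start, col_stop), with its position jittered
    by up to ``jitter`` pixels per image.  Spatially specific features
    (HOG, pixel intensities) should localize the difference to the region;
    Fourier magnitudes should pick up the bar's orientation/frequency
    signature without localizing it.

    Returns the image set and the region rectangle (useful as ground truth
    for where flagged features ought to concentrate).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    r0, r1, c0, c1 = region

    def background() -> np.ndarray:
        # smooth noise: white noise blurred by a small box filter
        raw = rng.random((size + 8, size + 8))
        k = 5
        csum = np.cumsum(np.cumsum(raw, axis=0), axis=1)
        sm = (csum[k:, k:] - csum[:-k, k:] - csum[k:, :-k] + csum[:-k, :-k]) / k**2
        return np.clip(sm[:size, :size], 0.0, 1.0)

    images, labels = [], []
    for label in (1, 2):
        for _ in range(n_per_class):
            img = background()
            if label == 2:
                dr = int(rng.integers(-jitter, jitter + 1))
                dc = int(rng.integers(-jitter, jitter + 1))
                rr0, rr1 = max(r0 + dr, 0), min(r1 + dr, size)
                cc0, cc1 = max(c0 + dc, 0), min(c1 + dc, size)
                img[rr0:rr1, cc0:cc1] = np.clip(
                    img[rr0:rr1, cc0:cc1] - contrast, 0.0, 1.0)
            images.append(img[:, :, None])
            labels.append(label)
    sources = [f"synthetic:{i}" for i in range(len(images))]
    return ImageSet(images, np.array(labels), sources, "gray", ["gray"]), region
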