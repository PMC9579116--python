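"""Human-readable summaries, covariate tables, and feature weight maps.

The reports are deterministic functions of the run configuration and the
significance results, so two identical runs produce byte-identical text.
The feature table maps each image onto its values for the significant
features, ready for use as covariates in a follow-up analysis; weight maps
place each significant feature's mean associated accuracy back onto the
native grid of its feature space.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .features import SPACE_COORDS, FeatureMatrix
from .significance import METHODS, SignificanceResult

__all__ = [
    "write_methods_text",
    "write_results_text",
    "write_feature_table",
    "weight_map",
]

#: feature spaces with a native grid a weight map can be drawn on
_SPATIAL_SPACES = ("fourier_magnitude", "fourier_phase", "hog", "pixel_intensity")

_CLASSIFIER_NAMES = {"linear_svm": "linear support vector machine"}


def write_methods_text(config: dict, path: str | Path | None = None) -> str:
    """Render a methods paragraph from a run-configuration snapshot."""
    k = config.get("k", 10)
    classifier = _CLASSIFIER_NAMES.get(config.get("classifier", "linear_svm"),
                                       str(config.get("classifier")))
    alpha = config.get("alpha", 0.01)
    shuffles = config.get("shuffles", 25)
    percentile = config.get("percentile", 99.0)
    r2 = config.get("r2_threshold", 0.25)
    spaces = config.get("spaces")
    wrapper = config.get("wrapper", {})

    lines = [
        "Methods",
        "=======",
        "",
        (f"Features were analyzed with {k}-fold cross-validation: in each fold one "
         "subset of examples was held out and used only to estimate model "
         "performance."),
    ]
    if spaces:
        lines.append("Feature spaces analyzed: " + ", ".join(spaces) + ".")
    lines += [
        (f"Within each fold, features were ranked by Kruskal-Wallis chi-square "
         f"scores and features sharing at least {100 * r2:.0f}% of their variance "
         "with a higher-ranking feature were clustered and selected together."),
        (f"Four selections were formed per fold: a filter selection (features at "
         f"p < {alpha:g}, or the best-performing top-ranking prefix if none "
         "passed), a stepwise wrapper selection grown to the filter selection's "
         "size, and random and pseudorandom selections of equal size."),
    ]
    if wrapper:
        lines.append(
            f"The wrapper searched the top "
            f"{wrapper.get('search_space_factor', 2):g}x the target number of "
            f"ranked features, admitted at most "
            f"{100 * wrapper.get('include_fraction', 0.25):.0f}% of the target per "
            f"iteration, pruned once the selection exceeded "
            f"{100 * wrapper.get('prune_trigger', 0.75):.0f}% of the target, and "
            f"averaged performance changes over {wrapper.get('repeats', 4)} fresh "
            "balanced splits.")
    lines += [
        (f"Selections were evaluated with a {classifier} trained on balanced "
         "training data and scored on the holdout examples; a full model using "
         "all features served as reference."),
        (f"Chance performance was estimated by retraining every selection "
         f"{shuffles} times per fold with shuffled labels ({k} x {shuffles} x 4 "
         "values). Features associated with performance above the "
         f"{percentile:g}th percentile of this distribution were flagged as "
         "relevant when their mean associated accuracy exceeded the maximum of a "
         "control distribution of equally sized averages resampled from the "
         "chance distribution (correcting for regression to the mean)."),
        "",
    ]
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text


def write_results_text(sig: SignificanceResult, path: str | Path | None = None) -> str:
    """Render a results overview: per-method accuracies, p-values, feature counts."""
    perf = sig.method_performance
    lines = ["Results", "=======", ""]
    for m in METHODS:
        lines.append(f"{m}: mean holdout accuracy "
                     f"{perf[m].mean():.3f} (p = {sig.method_p[m]:.4g})")
    lines.append(f"full model: mean holdout accuracy {perf['full'].mean():.3f}")
    lines.append("")
    lines.append("Per-fold holdout accuracy:")
    lines.append("fold  " + "  ".join(f"{m:>12s}" for m in perf.columns))
    for fold, row in perf.iterrows():
        lines.append(f"{fold:>4d}  " + "  ".join(f"{v:12.3f}" for v in row))
    lines.append("")

    n_rel = len(sig.relevant_features)
    if n_rel == 0:
        lines.append("Zero significant features were found.")
    else:
        lines.append(f"{n_rel} significant feature(s):")
        if sig.feature_meta is not None:
            counts = (sig.feature_meta.iloc[sig.relevant_features]
                      .groupby("space").size())
            for space, cnt in counts.items():
                lines.append(f"  {space}: {cnt}")
    lines.append("")
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text


def write_feature_table(
    features: FeatureMatrix,
    sig: SignificanceResult,
    path: str | Path,
) -> pd.DataFrame:
    """Write one row per image: source filename, then each significant feature.

    The resulting table is directly usable as covariates in a follow-up
    analysis of behavioral or neural responses to the same images.
    """
    rel = np.asarray(sig.relevant_features, dtype=int)
    if rel.size == 0:
        warnings.warn("no significant features; writing a header-only table")
    df = pd.DataFrame(features.values[:, rel],
                      columns=[f"feature_{i}" for i in rel])
    df.insert(0, "filename", features.sources)
    df.to_csv(path, index=False)
    return df


def weight_map(sig: SignificanceResult, space: str) -> np.ndarray:
    """Mean associated accuracy of flagged features on the space's native grid.

    Grid axes follow the space's coordinates (e.g. SF band x orientation
    band for Fourier magnitudes; cell row x cell column x orientation bin
    for HOG).  Non-flagged positions hold NaN as background.  Multi-layer
    runs produce a leading layer axis.
    """
    if space not in _SPATIAL_SPACES:
        raise ValueError(
            f"{space!r} has no spatial/band layout; export its features as a "
            "table instead")
    if sig.feature_meta is None:
        raise ValueError("significance result carries no feature metadata")
    meta = sig.feature_meta
    in_space = meta["space"] == space
    if not in_space.any():
        raise ValueError(f"no features of space {space!r} in this run")
    coord_names = SPACE_COORDS[space]
    coord_cols = ["c0", "c1", "c2"][: len(coord_names)]
    sub = meta.loc[in_space, ["layer"] + coord_cols].astype(int)
    n_layers = sub["layer"].max() + 1
    shape = tuple(sub[c].max() + 1 for c in coord_cols)
    grid = np.full((n_layers,) + shape, np.nan)

    flagged = sig.feature_stats["flagged"].to_numpy()
    perf = sig.feature_stats["mean_perf"].to_numpy()
    for feat in np.flatnonzero(in_space.to_numpy() & flagged):
        row = meta.iloc[feat]
        pos = (int(row["layer"]),) + tuple(int(row[c]) for c in coord_cols)
        grid[pos] = perf[feat]
    return grid[0] if n_layers == 1 else grid
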