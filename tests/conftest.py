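"""Shared fixtures: tiny synthetic image sets and feature matrices."""

import numpy as np
import pandas as pd
import pytest

from featsieve import FeatureMatrix, ImageSet


def make_feature_matrix(values, labels, link_groups=None, space="mock"):
    """FeatureMatrix with minimal metadata for selection/significance tests."""
    values = np.asarray(values, dtype=float)
    n_feat = values.shape[1]
    meta = pd.DataFrame({"space": space, "layer": 0,
                         "c0": np.arange(n_feat, dtype=float),
                         "c1": np.nan, "c2": np.nan})
    if link_groups is None:
        link_groups = np.arange(n_feat)
    return FeatureMatrix(values, labels, meta, link_groups)


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture
def gray_image_set(rng):
    """8 single-layer noise images, two classes, 40x40 pixels."""
    images = [rng.random((40, 40))[:, :, None] for _ in range(8)]
    labels = np.array([1, 1, 1, 1, 2, 2, 2, 2])
    return ImageSet(images, labels, [f"synthetic:{i}" for i in range(8)],
                    "gray", ["gray"])


@pytest.fixture
def rgb_image_set(rng):
    """6 three-layer noise images, two classes, 30x30 pixels."""
    images = [rng.random((30, 30, 3)) for _ in range(6)]
    labels = np.array([1, 1, 1, 2, 2, 2])
    return ImageSet(images, labels, [f"synthetic:{i}" for i in range(6)],
                    "rgb", ["R", "G", "B"])


@pytest.fixture
def separable_matrix(rng):
    """40 examples x 10 features; feature 0 separates the classes perfectly."""
    X = rng.normal(size=(40, 10))
    y = np.repeat([1, 2], 20)
    X[:20, 0] = rng.uniform(2.0, 3.0, 20)
    X[20:, 0] = rng.uniform(-3.0, -2.0, 20)
    return make_feature_matrix(X, y)
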