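"""Feature extraction from categorized images.

Turns a set of labelled images into an examples-by-features matrix over one or
more of five interpretable feature spaces:

* ``fourier_magnitude`` — the 2-D FFT magnitude spectrum pooled into spatial
  frequency x orientation bands (position invariant; global contrast content).
* ``fourier_phase`` — phase angles (optionally with the matching magnitudes)
  of the FFT of a downscaled copy of the image (weakly position specific).
* ``hog`` — histograms of oriented gradients in non-overlapping cells
  (position specific; local edge content).
* ``color_histogram`` — per-layer value distributions over fixed bins
  (position invariant; global color content).
* ``pixel_intensity`` — raw intensities of a downscaled copy (position
  specific).

Every feature carries provenance metadata (feature space, image layer and the
band/cell/bin coordinates it came from) so that selection results can be
mapped back onto the image, and a *link group* id: features sharing a link
group are always selected together downstream (corresponding positions across
color layers, or a phase/magnitude pair).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.color import rgb2gray, rgb2lab
from skimage.transform import resize

__all__ = [
    "FeatureExtractionConfig",
    "ImageSet",
    "FeatureMatrix",
    "load_image_set",
    "extract_fourier_magnitude",
    "extract_fourier_phase",
    "extract_hog",
    "extract_color_histogram",
    "extract_pixel_intensities",
    "extract_features",
    "pairwise_feature_differences",
    "concat_features",
    "fourier_band_labels",
    "FEATURE_SPACES",
]

FEATURE_SPACES = (
    "fourier_magnitude",
    "fourier_phase",
    "hog",
    "color_histogram",
    "pixel_intensity",
)

#: native coordinate names per feature space, in feature_meta column order
#: ("c0", "c1", "c2"); unused coordinates are NaN.
SPACE_COORDS = {
    "fourier_magnitude": ("sf_band", "ori_band"),
    "fourier_phase": ("row", "col", "component"),  # component: 0=phase, 1=magnitude
    "hog": ("cell_row", "cell_col", "ori_bin"),
    "color_histogram": ("bin",),
    "pixel_intensity": ("row", "col"),
}

#: fixed histogram ranges per layer name, so color bins are comparable
#: across images (per-image min-max binning would destroy that).
LAYER_RANGES = {
    "gray": (0.0, 1.0),
    "R": (0.0, 1.0),
    "G": (0.0, 1.0),
    "B": (0.0, 1.0),
    "L": (0.0, 100.0),
    "a": (-128.0, 127.0),
    "b": (-128.0, 127.0),
}


@dataclass
class FeatureExtractionConfig:
    """Knobs of the five extractors.

    Defaults follow the toolbox conventions: 24 spatial-frequency by 16
    orientation bands (384 Fourier-magnitude features per layer), 9 unsigned
    HOG orientations over non-overlapping 10x10-pixel cells, 25 color bins,
    and a 25x25 downscale for the phase and pixel-intensity spaces.
    """

    sf_bands: int = 24
    ori_bands: int = 16
    hog_orientations: int = 9
    hog_cell: int = 10
    color_bins: int = 25
    downsample_size: int = 25
    link_layers: bool = True
    include_dc: bool = True  # DC term -> lowest SF band, orientation sector 0

    def __post_init__(self) -> None:
        for name in ("sf_bands", "ori_bands", "hog_orientations", "hog_cell",
                     "color_bins", "downsample_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")


@dataclass
class ImageSet:
    """Labelled images in a common colorspace with a common layer count."""

    images: list[np.ndarray]  # each (H, W, L), float
    labels: np.ndarray  # positive integers, one per image
    sources: list[str]  # file paths or "synthetic:<i>"
    colorspace: str  # gray | rgb | lab
    layer_names: list[str]  # e.g. ["L", "a", "b"] after layer selection

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.images) != len(self.labels):
            raise ValueError("one label per image required")
        layers = {im.shape[2] for im in self.images}
        if len(layers) > 1:
            raise ValueError(f"images disagree on layer count: {sorted(layers)}")
        if np.unique(self.labels).size < 2:
            raise ValueError("an ImageSet needs at least 2 distinct labels")

    @property
    def n_layers(self) -> int:
        return self.images[0].shape[2]

    def __len__(self) -> int:
        return len(self.images)


@dataclass
class FeatureMatrix:
    """Examples x features with labels, per-feature provenance and link groups.

    ``feature_meta`` has one row per column of ``values`` with columns
    ``space``, ``layer``, ``c0``, ``c1``, ``c2`` (native coordinates per
    :data:`SPACE_COORDS`).  ``link_groups`` holds an integer per feature;
    features sharing a value must be selected together.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_meta: pd.DataFrame
    link_groups: np.ndarray
    sources: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.link_groups = np.asarray(self.link_groups, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (examples x features)")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")
        if len(self.feature_meta) != self.values.shape[1]:
            raise ValueError("feature_meta length must equal the feature count")
        if self.link_groups.shape[0] != self.values.shape[1]:
            raise ValueError("link_groups length must equal the feature count")
        if not self.sources:
            self.sources = [f"synthetic:{i}" for i in range(self.values.shape[0])]

    @property
    def n_examples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def to_csv(self, data_path: str | Path, meta_path: str | Path) -> None:
        """Write the matrix (label + features per row) and the sidecar metadata."""
        df = pd.DataFrame(self.values, columns=[f"f{i}" for i in range(self.n_features)])
        df.insert(0, "label", self.labels)
        df.insert(0, "source", self.sources)
        df.to_csv(data_path, index=False)
        meta = self.feature_meta.copy()
        meta.insert(0, "feature", np.arange(self.n_features))
        meta["link_group"] = self.link_groups
        meta.to_csv(meta_path, index=False)

    @classmethod
    def from_csv(cls, data_path: str | Path, meta_path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(data_path)
        if "label" not in df.columns:
            raise ValueError(f"{data_path}: missing 'label' column")
        sources = df["source"].astype(str).tolist() if "source" in df.columns else []
        labels = df["label"].to_numpy()
        values = df.drop(columns=[c for c in ("source", "label") if c in df.columns]).to_numpy(float)
        meta = pd.read_csv(meta_path)
        link = meta["link_group"].to_numpy(int)
        meta = meta.drop(columns=["feature", "link_group"], errors="ignore")
        return cls(values, labels, meta, link, sources)


# ---------------------------------------------------------------------------
# Image loading
# ---------------------------------------------------------------------------

_LAYER_NAMES = {"gray": ["gray"], "rgb": ["R", "G", "B"], "lab": ["L", "a", "b"]}


def _read_normalized(path: str | Path) -> np.ndarray:
    """Read a raster image to float in [0, 1] (RGB kept, alpha dropped)."""
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoding failure
        raise OSError(f"cannot read image file {path!r}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.dtype == np.uint8:
        arr = arr.astype(float) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(float) / 65535.0
    else:
        arr = arr.astype(float)
        if arr.max() > 1.0:
            arr = arr / 255.0
    return arr


def _convert(arr: np.ndarray, color_mode: str) -> np.ndarray:
    """Convert a [0,1] array to the requested colorspace, always (H, W, L)."""
    is_rgb = arr.ndim == 3 and arr.shape[2] == 3
    if color_mode == "gray":
        out = rgb2gray(arr) if is_rgb else arr.squeeze()
        return out[:, :, None]
    if not is_rgb:
        raise ValueError(f"color_mode={color_mode!r} requires RGB input")
    if color_mode == "rgb":
        return arr
    if color_mode == "lab":
        return rgb2lab(arr)  # sRGB input, D65 white point
    raise ValueError(f"unknown color_mode {color_mode!r}")


def load_image_set(
    paths_or_label_file: Sequence[str | Path] | str | Path,
    color_mode: str = "gray",
    layers: Iterable[int] | None = None,
) -> ImageSet:
    """Load categorized images from directories or a label-list file.

    Parameters
    ----------
    paths_or_label_file
        Either a list of directories (directory order defines the label
        numbering 1, 2, ...; files within a directory are taken in sorted
        order) or a path to a CSV file with header ``label,filepath``.
    color_mode
        ``gray`` (luminance), ``rgb``, or ``lab`` (CIELAB from sRGB, D65).
    layers
        Optional 1-based subset of layers to keep after conversion, e.g.
        ``(2, 3)`` with ``lab`` keeps the a* and b* opponent layers.
    """
    if isinstance(paths_or_label_file, (str, Path)):
        table = pd.read_csv(paths_or_label_file)
        cols = [c.strip().lower() for c in table.columns]
        if "label" not in cols or "filepath" not in cols:
            raise ValueError(
                f"label file {paths_or_label_file!r} needs columns 'label' and 'filepath'"
            )
        table.columns = cols
        try:
            labels = table["label"].astype(float).to_numpy()
        except (TypeError, ValueError) as exc:
            raise ValueError(f"label file {paths_or_label_file!r}: non-numeric labels") from exc
        if not np.all(labels == labels.astype(int)):
            raise ValueError(f"label file {paths_or_label_file!r}: labels must be integers")
        labels = labels.astype(int)
        files = [Path(p) for p in table["filepath"]]
    else:
        files, labels_list = [], []
        for lab_id, d in enumerate(paths_or_label_file, start=1):
            d = Path(d)
            if not d.is_dir():
                raise OSError(f"not a directory: {d}")
            entries = sorted(p for p in d.iterdir() if p.is_file())
            if not entries:
                raise ValueError(f"directory {d} contains no files")
            files.extend(entries)
            labels_list.extend([lab_id] * len(entries))
        labels = np.asarray(labels_list, dtype=int)

    images = [_convert(_read_normalized(f), color_mode) for f in files]
    names = list(_LAYER_NAMES[color_mode])
    if layers is not None:
        sel = sorted(set(int(i) for i in layers))
        if any(i < 1 or i > images[0].shape[2] for i in sel):
            raise ValueError(f"layer selection {sel} out of range for {color_mode}")
        images = [im[:, :, [i - 1 for i in sel]] for im in images]
        names = [names[i - 1] for i in sel]
    return ImageSet(images, labels, [str(f) for f in files], color_mode, names)


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------

def _central_square(img: np.ndarray) -> np.ndarray:
    """Central square crop (keeps the FFT band geometry isotropic)."""
    h, w = img.shape[:2]
    n = min(h, w)
    r0, c0 = (h - n) // 2, (w - n) // 2
    return img[r0:r0 + n, c0:c0 + n]


def _downscale(layer: np.ndarray, size: int) -> np.ndarray:
    """Bicubic downscale with antialiasing, preserving the value range."""
    if layer.shape == (size, size):
        return layer
    return resize(layer, (size, size), order=3, anti_aliasing=True,
                  preserve_range=True, mode="reflect")


def _make_meta(space: str, n_layers: int, coords: np.ndarray) -> pd.DataFrame:
    """Tile per-layer coordinates into a full meta table (layer-major order)."""
    per_layer = coords.shape[0]
    c = np.full((n_layers * per_layer, 3), np.nan)
    c[:, :coords.shape[1]] = np.tile(coords, (n_layers, 1))
    return pd.DataFrame({
        "space": space,
        "layer": np.repeat(np.arange(n_layers), per_layer),
        "c0": c[:, 0], "c1": c[:, 1], "c2": c[:, 2],
    })


_GROUP_COUNTER = [0]


def _fresh_groups(n: int) -> np.ndarray:
    """Globally unique singleton link-group ids (safe to concatenate spaces)."""
    start = _GROUP_COUNTER[0]
    _GROUP_COUNTER[0] += n
    return np.arange(start, start + n)


def _layer_link_groups(n_layers: int, per_layer: int, link_layers: bool) -> np.ndarray:
    """Link corresponding positions across layers when requested."""
    if link_layers and n_layers > 1:
        base = _fresh_groups(per_layer)
        return np.tile(base, n_layers)
    return _fresh_groups(n_layers * per_layer)


# ---------------------------------------------------------------------------
# Fourier magnitude bands
# ---------------------------------------------------------------------------

def fourier_band_labels(n: int, cfg: FeatureExtractionConfig) -> np.ndarray:
    """Band-index map for an n x n fftshifted spectrum.

    Returns an (n, n) integer array: ``sf_band * ori_bands + ori_band`` per
    spectral position, or -1 for positions outside the band grid.  Bands are
    equal-width annuli in normalized frequency radius (0, 1] (1 = Nyquist;
    corner positions beyond the Nyquist radius are excluded) crossed with 16
    equal orientation sectors partitioning [0, 180) degrees.  The DC term is
    assigned to the lowest-frequency band at sector 0 when
    ``cfg.include_dc``, else excluded.
    """
    half = n / 2.0
    freq = np.arange(n) - n // 2  # fftshifted coordinates
    fy, fx = np.meshgrid(freq, freq, indexing="ij")
    r = np.hypot(fx, fy) / half
    theta = np.mod(np.degrees(np.arctan2(fy, fx)), 180.0)

    sf = np.ceil(r * cfg.sf_bands).astype(int) - 1  # (0,1] -> 0..sf_bands-1
    sf = np.clip(sf, 0, None)
    ori = np.minimum((theta / 180.0 * cfg.ori_bands).astype(int), cfg.ori_bands - 1)

    labels = sf * cfg.ori_bands + ori
    labels[r > 1.0] = -1
    dc = (r == 0)
    labels[dc] = 0 if cfg.include_dc else -1
    return labels


def extract_fourier_magnitude(images: ImageSet, cfg: FeatureExtractionConfig | None = None) -> FeatureMatrix:
    """Fourier magnitude spectrum pooled into SF x orientation bands.

    Each feature is the sum of 2-D FFT magnitudes whose polar coordinates
    fall in one spatial-frequency/orientation section; with defaults, 24 x 16
    = 384 features per layer.  The pooling discards phase, so the features
    are invariant to circular translation of the image.
    """
    cfg = cfg or FeatureExtractionConfig()
    n_bands = cfg.sf_bands * cfg.ori_bands
    n_layers = images.n_layers
    out = np.empty((len(images), n_layers * n_bands))
    label_cache: dict[int, np.ndarray] = {}
    for i, img in enumerate(images.images):
        sq = _central_square(img)
        n = sq.shape[0]
        if n < 2:
            raise ValueError(f"image {i} smaller than 2x2 after square crop")
        if n not in label_cache:
            label_cache[n] = fourier_band_labels(n, cfg).ravel()
        lab = label_cache[n]
        keep = lab >= 0
        for l in range(n_layers):
            mag = np.abs(np.fft.fftshift(np.fft.fft2(sq[:, :, l]))).ravel()
            out[i, l * n_bands:(l + 1) * n_bands] = np.bincount(
                lab[keep], weights=mag[keep], minlength=n_bands)
    coords = np.array([(b, o) for b in range(cfg.sf_bands) for o in range(cfg.ori_bands)], float)
    meta = _make_meta("fourier_magnitude", n_layers, coords)
    groups = _layer_link_groups(n_layers, n_bands, cfg.link_layers)
    return FeatureMatrix(out, images.labels, meta, groups, list(images.sources))


def extract_fourier_phase(
    images: ImageSet,
    cfg: FeatureExtractionConfig | None = None,
    include_magnitude: bool = False,
) -> FeatureMatrix:
    """Phase (optionally plus magnitude) of the FFT of a downscaled image.

    The image is downscaled to ``downsample_size`` squared before the FFT, so
    the spectrum stays small (625 phase features per layer at defaults).
    When magnitudes are included, each phase/magnitude pair shares a link
    group so the pair always enters or leaves a selection together.
    """
    cfg = cfg or FeatureExtractionConfig()
    s = cfg.downsample_size
    per = s * s
    n_layers = images.n_layers
    per_layer = per * (2 if include_magnitude else 1)
    out = np.empty((len(images), n_layers * per_layer))
    for i, img in enumerate(images.images):
        sq = _central_square(img)
        for l in range(n_layers):
            spec = np.fft.fftshift(np.fft.fft2(_downscale(sq[:, :, l], s)))
            block = out[i, l * per_layer:(l + 1) * per_layer]
            block[:per] = np.angle(spec).ravel()
            if include_magnitude:
                block[per:] = np.abs(spec).ravel()

    rc = np.array([(r, c) for r in range(s) for c in range(s)], float)
    coords = np.hstack([rc, np.zeros((per, 1))])
    if include_magnitude:
        coords = np.vstack([coords, np.hstack([rc, np.ones((per, 1))])])
    meta = _make_meta("fourier_phase", n_layers, coords)

    # phase/magnitude pairs share a group; layers optionally linked on top
    if cfg.link_layers and n_layers > 1:
        base = _fresh_groups(per)
        layer_groups = np.tile(base, 2) if include_magnitude else base
        groups = np.tile(layer_groups, n_layers)
    else:
        groups = np.concatenate([
            np.tile(_fresh_groups(per), 2) if include_magnitude else _fresh_groups(per)
            for _ in range(n_layers)
        ])
    return FeatureMatrix(out, images.labels, meta, groups, list(images.sources))


# ---------------------------------------------------------------------------
# HOG
# ---------------------------------------------------------------------------

def _hog_layer(layer: np.ndarray, cfg: FeatureExtractionConfig) -> np.ndarray:
    """Per-cell unsigned orientation histograms of gradient magnitude.

    Centered finite differences, linear interpolation of each pixel's
    magnitude between the two adjacent orientation bins, plain per-cell sums
    with no block normalization — each feature reads as the summed edge
    energy at one orientation in one cell.
    """
    cell, nb = cfg.hog_cell, cfg.hog_orientations
    cy, cx = layer.shape[0] // cell, layer.shape[1] // cell
    if cy < 1 or cx < 1:
        raise ValueError("image smaller than one HOG cell")
    crop = layer[:cy * cell, :cx * cell]  # drop bottom/right remainder
    gy, gx = np.gradient(crop)
    mag = np.hypot(gx, gy)
    ang = np.mod(np.arctan2(gy, gx), np.pi)  # unsigned, [0, pi)

    width = np.pi / nb
    pos = ang / width - 0.5
    b0 = np.floor(pos).astype(int) % nb
    frac = pos - np.floor(pos)
    b1 = (b0 + 1) % nb

    rows = np.arange(cy * cell) // cell
    cols = np.arange(cx * cell) // cell
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    hist = np.zeros((cy, cx, nb))
    np.add.at(hist, (rr, cc, b0), mag * (1 - frac))
    np.add.at(hist, (rr, cc, b1), mag * frac)
    return hist.ravel()  # row-major: (cell_row, cell_col, ori_bin)


def extract_hog(images: ImageSet, cfg: FeatureExtractionConfig | None = None) -> FeatureMatrix:
    """Histogram-of-oriented-gradients features over non-overlapping cells."""
    cfg = cfg or FeatureExtractionConfig()
    cell, nb = cfg.hog_cell, cfg.hog_orientations
    h, w = images.images[0].shape[:2]
    if any(im.shape[:2] != (h, w) for im in images.images):
        raise ValueError("HOG extraction requires images of equal size")
    cy, cx = h // cell, w // cell
    if cy < 1 or cx < 1:
        raise ValueError("image smaller than one HOG cell")
    per_layer = cy * cx * nb
    n_layers = images.n_layers
    out = np.empty((len(images), n_layers * per_layer))
    for i, img in enumerate(images.images):
        for l in range(n_layers):
            out[i, l * per_layer:(l + 1) * per_layer] = _hog_layer(img[:, :, l], cfg)
    coords = np.array(
        [(r, c, o) for r in range(cy) for c in range(cx) for o in range(nb)], float)
    meta = _make_meta("hog", n_layers, coords)
    groups = _layer_link_groups(n_layers, per_layer, cfg.link_layers)
    return FeatureMatrix(out, images.labels, meta, groups, list(images.sources))


# ---------------------------------------------------------------------------
# Color histograms
# ---------------------------------------------------------------------------

def extract_color_histogram(images: ImageSet, cfg: FeatureExtractionConfig | None = None) -> FeatureMatrix:
    """Per-layer value distributions over fixed bins (probability vectors).

    Bin edges are fixed per layer type (gray/RGB over [0, 1]; L* over
    [0, 100]; a*/b* over [-128, 127]) so histograms are comparable across
    images.  Features are never linked across layers: a bin of the a* layer
    has no meaningful counterpart in the b* layer.
    """
    cfg = cfg or FeatureExtractionConfig()
    nb = cfg.color_bins
    n_layers = images.n_layers
    out = np.empty((len(images), n_layers * nb))
    for i, img in enumerate(images.images):
        for l, name in enumerate(images.layer_names):
            lo, hi = LAYER_RANGES[name]
            vals = np.clip(img[:, :, l].ravel(), lo, hi)
            counts, _ = np.histogram(vals, bins=nb, range=(lo, hi))
            out[i, l * nb:(l + 1) * nb] = counts / counts.sum()
    coords = np.arange(nb, dtype=float)[:, None]
    meta = _make_meta("color_histogram", n_layers, coords)
    groups = _fresh_groups(n_layers * nb)  # never linked across layers
    return FeatureMatrix(out, images.labels, meta, groups, list(images.sources))


# ---------------------------------------------------------------------------
# Pixel intensities
# ---------------------------------------------------------------------------

def extract_pixel_intensities(images: ImageSet, cfg: FeatureExtractionConfig | None = None) -> FeatureMatrix:
    """Raw intensities of a bicubically downscaled copy, flattened row-major."""
    cfg = cfg or FeatureExtractionConfig()
    s = cfg.downsample_size
    per = s * s
    n_layers = images.n_layers
    out = np.empty((len(images), n_layers * per))
    for i, img in enumerate(images.images):
        for l in range(n_layers):
            out[i, l * per:(l + 1) * per] = _downscale(img[:, :, l], s).ravel()
    coords = np.array([(r, c) for r in range(s) for c in range(s)], float)
    meta = _make_meta("pixel_intensity", n_layers, coords)
    groups = _layer_link_groups(n_layers, per, cfg.link_layers)
    return FeatureMatrix(out, images.labels, meta, groups, list(images.sources))


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

_EXTRACTORS = {
    "fourier_magnitude": extract_fourier_magnitude,
    "fourier_phase": extract_fourier_phase,
    "hog": extract_hog,
    "color_histogram": extract_color_histogram,
    "pixel_intensity": extract_pixel_intensities,
}


def extract_features(
    images: ImageSet,
    spaces: Sequence[str],
    cfg: FeatureExtractionConfig | None = None,
) -> FeatureMatrix:
    """Extract and horizontally concatenate one or more feature spaces."""
    cfg = cfg or FeatureExtractionConfig()
    unknown = set(spaces) - set(_EXTRACTORS)
    if unknown:
        raise ValueError(f"unknown feature spaces: {sorted(unknown)}")
    mats = [_EXTRACTORS[s](images, cfg) for s in spaces]
    return concat_features(mats)


def concat_features(mats: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Concatenate feature matrices over the same examples."""
    if len(mats) == 1:
        return mats[0]
    first = mats[0]
    for m in mats[1:]:
        if not np.array_equal(m.labels, first.labels):
            raise ValueError("feature matrices disagree on labels")
    values = np.hstack([m.values for m in mats])
    meta = pd.concat([m.feature_meta for m in mats], ignore_index=True)
    groups = np.concatenate([m.link_groups for m in mats])
    return FeatureMatrix(values, first.labels, meta, groups, list(first.sources))


def pairwise_feature_differences(
    features: FeatureMatrix,
    pairs: Sequence[tuple[int, int, int]],
) -> FeatureMatrix:
    """Feature differences for image pairs, labelled per pair.

    Supports designs where the unit of analysis is a choice between two
    images (e.g. which of two stimuli a participant selected): each output
    example is ``features[a] - features[b]`` with the supplied label.
    """
    n = features.n_examples
    for a, b, _ in pairs:
        if not (0 <= a < n and 0 <= b < n):
            raise ValueError(f"pair index out of range: ({a}, {b}) with {n} examples")
    values = np.array([features.values[a] - features.values[b] for a, b, _ in pairs])
    labels = np.array([lab for _, _, lab in pairs], dtype=int)
    sources = [f"pair({features.sources[a]},{features.sources[b]})" for a, b, _ in pairs]
    return FeatureMatrix(values, labels, features.feature_meta.copy(),
                         features.link_groups.copy(), sources)
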