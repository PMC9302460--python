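"""Stimulus attributes: visual confound features and class discretization.

Picture-naming stimuli come with lexical attributes (syllable count,
phonological neighborhood density, SUBTLEX frequency per million) and with
low-level visual properties of the images themselves (contrast, edge
density, colorfulness).  Decoding contrasts operate on discretized class
labels derived here; the visual features additionally define the strata
used to constrain the permutation null of the category contrast.

All operators are pure functions: the same inputs always yield the same
labels and feature values.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "discretize_quantiles",
    "discretize_bounds",
    "median_split",
    "to_grayscale",
    "contrast",
    "edge_density",
    "colorfulness",
    "correlate_attributes",
    "load_image",
    "DENSITY_CLASS_NAMES",
]

#: ordered names for the four neighborhood-density classes
DENSITY_CLASS_NAMES = ("smaller", "small", "large", "larger")

# Luminance weights for grayscale conversion (ITU-R BT.601).
_LUMA = np.array([0.299, 0.587, 0.114])

# Sobel kernels; for intensities in [0, 1] the per-axis response is bounded
# by 4, hence the gradient magnitude by 4*sqrt(2).
_SOBEL_MAX_MAGNITUDE = 4.0 * np.sqrt(2.0)
#: fixed edge threshold: 10% of the maximum possible gradient magnitude
EDGE_THRESHOLD_FRAC = 0.1


def discretize_quantiles(values, n_classes: int, names: tuple[str, ...] | None = None):
    """Rank-based split into ``n_classes`` classes of near-equal size.

    Values are ordered and cut at ranks ``round(k*n/n_classes)``; tied
    values always share a label, and a tied run spanning a cut is assigned
    to the lower class, so the split is a pure function of the values.

    Returns an integer array of class indices (0 = smallest values), or an
    object array of ``names`` when given.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if n < n_classes:
        raise ValueError("need at least n_classes values")
    if np.unique(values).size == 1:
        warnings.warn("all values identical: a single class is returned")
        labels = np.zeros(n, dtype=int)
    else:
        order = np.argsort(values, kind="stable")
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(n)
        cuts = np.round(np.arange(1, n_classes) * n / n_classes).astype(int)
        labels = np.searchsorted(cuts, ranks, side="right")
        # ties share the label of their lowest-ranked member
        for val in np.unique(values):
            sel = values == val
            labels[sel] = labels[sel].min()
    if names is not None:
        if len(names) < n_classes:
            raise ValueError("not enough names for n_classes")
        return np.asarray(names, dtype=object)[labels]
    return labels


def discretize_bounds(values, bounds, names: tuple[str, ...] | None = None):
    """Split at explicit closed-interval upper bounds.

    ``bounds`` are the inclusive upper edges of all classes but the last,
    e.g. ``(4, 9, 19)`` puts 0-4 / 5-9 / 10-19 / 20+ into four classes.
    """
    values = np.asarray(values, dtype=float)
    labels = np.searchsorted(np.asarray(bounds, dtype=float), values, side="left")
    if names is not None:
        return np.asarray(names, dtype=object)[labels]
    return labels


def median_split(values, names: tuple[str, str] = ("low", "high")):
    """Two classes of approximately equal size, ties to the lower class."""
    return discretize_quantiles(values, 2, names=names)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luminance grayscale (weights 0.299/0.587/0.114), intensities in [0, 1]."""
    image = _as_float01(image)
    if image.ndim == 2:
        return image
    return image @ _LUMA


def contrast(image: np.ndarray) -> float:
    """Mean local intensity variance in a 3x3 neighborhood.

    Operates on the [0, 1] grayscale image; each pixel contributes the
    variance of its 3x3 neighborhood (reflected at the border), and the
    image value is the mean over pixels.  Uniform images score 0 and the
    measure is invariant to adding a constant intensity.
    """
    gray = to_grayscale(image)
    if gray.size == 0:
        raise ValueError("empty image")
    if gray.size == 1:
        warnings.warn("1x1 image: contrast undefined, returning 0")
        return 0.0
    local_mean = ndimage.uniform_filter(gray, size=3, mode="reflect")
    local_sq = ndimage.uniform_filter(gray * gray, size=3, mode="reflect")
    local_var = np.clip(local_sq - local_mean**2, 0.0, None)
    return float(local_var.mean())


def edge_density(image: np.ndarray) -> float:
    """Percentage of pixels that are edge pixels.

    Edges are pixels whose Sobel gradient magnitude on the grayscale image
    exceeds a fixed fraction (10%) of the maximum magnitude attainable by a
    [0, 1] image, making the percentage well defined and reproducible.
    """
    gray = to_grayscale(image)
    if gray.size == 0:
        raise ValueError("empty image")
    gx = ndimage.sobel(gray, axis=1, mode="reflect")
    gy = ndimage.sobel(gray, axis=0, mode="reflect")
    mag = np.hypot(gx, gy)
    thresh = EDGE_THRESHOLD_FRAC * _SOBEL_MAX_MAGNITUDE
    return float(100.0 * np.mean(mag > thresh))


def colorfulness(image: np.ndarray) -> float:
    """Hasler-Suesstrunk colorfulness from opponent color statistics.

    With channels on a 0-255 scale, ``rg = R - G`` and
    ``yb = (R + G)/2 - B``:

        C = sqrt(sigma_rg^2 + sigma_yb^2) + 0.3 * sqrt(mu_rg^2 + mu_yb^2)

    A distributional statistic: invariant to shuffling pixel positions,
    and 0 for any image with R = G = B everywhere.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("colorfulness requires an H x W x 3 image")
    r, g, b = image[..., 0], image[..., 1], image[..., 2]
    rg = r - g
    yb = 0.5 * (r + g) - b
    sigma = np.sqrt(rg.std() ** 2 + yb.std() ** 2)
    mu = np.sqrt(rg.mean() ** 2 + yb.mean() ** 2)
    return float(sigma + 0.3 * mu)


def correlate_attributes(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Pearson correlation matrix among numeric stimulus attributes.

    Zero-variance columns yield NaN entries (flagged with a warning).
    """
    numeric = table.select_dtypes(include=[np.number]) if columns is None else table[list(columns)]
    if len(numeric) < 3:
        raise ValueError("need at least 3 items to correlate")
    corr = numeric.corr(method="pearson")
    degenerate = [c for c in numeric.columns if numeric[c].std() == 0]
    if degenerate:
        warnings.warn(f"zero-variance columns, correlations undefined: {degenerate}")
    return corr


def load_image(path) -> np.ndarray:
    """Read a PNG (or any Pillow-readable) image as an RGB float array (0-255)."""
    from PIL import Image

    with Image.open(path) as img:
        return np.asarray(img.convert("RGB"), dtype=float)


def _as_float01(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.size and image.max() > 1.0:
        image = image / 255.0
    return image
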