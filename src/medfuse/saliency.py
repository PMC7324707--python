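"""Global-contrast saliency from the intensity histogram.

The saliency of a pixel is its mean absolute intensity distance to every
other pixel in the image, so rare bright (or rare dark) intensities stand
out.  Because the distance depends only on intensity, pixels sharing a
quantized level share a saliency value, and the naive O(N^2) pairwise sum
collapses to a sum over histogram levels:

    S(c_l) = sum_j f_j * |c_l - c_j|

with f_j the empirical probability of level c_j.  Saliency is computed on
the integer level scale 0..levels-1 (256 levels matches 8-bit sources) and
is not renormalized — only its relative magnitude matters downstream.

High-intensity structures (skull on CT, bright lesions on MR-T2) dominate
the saliency map of the respective modality; thresholding the map yields a
binary mask of those structures, which seeds the fusion weight maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .errors import ValidationError
from .image_io import validate_image

__all__ = ["SaliencyMap", "quantize", "histogram_saliency", "binarize_saliency"]


@dataclass(frozen=True)
class SaliencyMap:
    """Per-pixel nonnegative saliency on the 0..levels-1 intensity scale."""

    values: np.ndarray
    levels: int

    def __array__(self, dtype=None, copy=None):
        if dtype is None:
            return self.values
        return self.values.astype(dtype)

    @property
    def shape(self):
        return self.values.shape


def quantize(img: np.ndarray, levels: int = 256) -> np.ndarray:
    """Quantize a [0, 1] image to integer levels 0..levels-1.

    Uses floor(value * (levels - 0.001)) so that 1.0 maps to the top level
    and k/(levels-1) maps back to k exactly for 8-bit-originated data.
    """
    if levels < 2:
        raise ValidationError(f"levels must be >= 2, got {levels}")
    arr = validate_image(img)
    q = np.floor(arr * (levels - 0.001)).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def histogram_saliency(img: np.ndarray, levels: int = 256) -> SaliencyMap:
    """Histogram-contrast saliency map of a grayscale image.

    Equivalent to the per-pixel mean absolute intensity distance to all
    pixels (including itself), evaluated in O(levels^2) via the histogram.
    A constant image has zero saliency everywhere.
    """
    q = quantize(img, levels)
    counts = np.bincount(q.ravel(), minlength=levels)
    freqs = counts / q.size
    grid = np.arange(levels, dtype=np.float64)
    # S(c_l) = sum_j f_j |c_l - c_j| for every level c_l
    distances = np.abs(grid[:, None] - grid[None, :])
    level_saliency = distances @ freqs
    return SaliencyMap(values=level_saliency[q], levels=levels)


def binarize_saliency(
    sal: SaliencyMap | np.ndarray,
    method: str = "otsu",
    fraction: float = 0.5,
) -> np.ndarray:
    """Threshold a saliency map into a {0,1} mask of salient pixels.

    ``method="otsu"`` picks the threshold by Otsu's criterion on the
    saliency histogram; ``method="fraction"`` thresholds at
    ``fraction * max(saliency)``.  Pixels strictly above the threshold get
    1.  An all-constant (e.g. all-zero) saliency map yields an all-zero
    mask rather than an error.
    """
    values = np.asarray(sal, dtype=np.float64)
    if not np.all(np.isfinite(values)) or values.min() < 0:
        raise ValidationError("saliency map must be finite and nonnegative")
    if values.max() == values.min():
        return np.zeros_like(values)
    if method == "otsu":
        thresh = threshold_otsu(values.ravel())
    elif method == "fraction":
        if not (0.0 < fraction < 1.0):
            raise ValidationError(
                f"fraction must be in (0, 1), got {fraction}"
            )
        thresh = fraction * values.max()
    else:
        raise ValidationError(f"unknown threshold method: {method!r}")
    return (values > thresh).astype(np.float64)
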