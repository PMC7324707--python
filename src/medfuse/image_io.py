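"""Grayscale image input/output and the co-registration contract.

Every stage of the fusion pipeline operates on 2-D ``float64`` arrays with
values in [0, 1] — the "image" currency of the package.  This module loads
PNG/TIFF rasters (and single slices of NIfTI volumes), normalizes them into
that currency, validates them, and writes results back out at a chosen bit
depth.  Pixel (0, 0) is the top-left corner; axis order is (row, column).

The package performs no registration: :func:`assert_registered_pair` only
checks that two images share a shape, which is the entire co-registration
contract the fusion method assumes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np

from .errors import RegistrationError, ValidationError

__all__ = [
    "LoadedImage",
    "read_image",
    "write_image",
    "validate_image",
    "assert_registered_pair",
    "normalize_to_unit",
]


@dataclass(frozen=True)
class LoadedImage:
    """A normalized grayscale image plus the bit depth it came from.

    ``values`` is a float64 array in [0, 1]; ``source_depth`` is ``"8"``,
    ``"16"`` or ``"float"``.  The object coerces to an array transparently,
    so it can be passed anywhere a plain image array is expected.
    """

    values: np.ndarray
    source_depth: str

    def __array__(self, dtype=None, copy=None):
        if dtype is None:
            return self.values
        return self.values.astype(dtype)

    @property
    def shape(self):
        return self.values.shape


def validate_image(img: np.ndarray, name: str = "image") -> np.ndarray:
    """Coerce to float64 and enforce the image invariants.

    Raises :class:`ValidationError` unless ``img`` is 2-D, at least 2x2,
    finite everywhere and contained in [0, 1].
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError(f"{name} must be 2-D, got ndim={arr.ndim}")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValidationError(
            f"{name} must be at least 2x2 (gradients must be definable), "
            f"got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValidationError(
            f"{name} values must lie in [0, 1], got range "
            f"[{arr.min():.6g}, {arr.max():.6g}]"
        )
    return arr


def normalize_to_unit(
    raw: np.ndarray, source_dtype: np.dtype | None = None
) -> tuple[np.ndarray, str]:
    """Map a raw decoded raster to float64 in [0, 1].

    Integer rasters are scaled by their dtype's full range ``2**depth - 1``;
    float rasters are min/max normalized (a constant float image maps to all
    zeros, so behavior on arbitrary inputs is deterministic).
    ``source_dtype`` overrides the dtype used for the scaling decision (a
    luminance-averaged integer raster arrives as float but keeps its
    integer scale).
    """
    dtype = np.dtype(source_dtype) if source_dtype is not None else raw.dtype
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        depth = info.bits
        out = raw.astype(np.float64) / float(2**depth - 1)
        return out, str(depth)
    arr = raw.astype(np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    if hi > lo:
        arr = (arr - lo) / (hi - lo)
    else:
        arr = np.zeros_like(arr)
    return arr, "float"


def _to_single_channel(raw: np.ndarray) -> np.ndarray:
    """Collapse a multi-channel raster to one channel by luminance average."""
    if raw.ndim == 3 and raw.shape[-1] in (2, 3, 4):
        # drop an alpha channel before averaging
        if raw.shape[-1] in (2, 4):
            raw = raw[..., :-1]
        return raw.mean(axis=-1)
    return raw


def read_image(
    path: str | os.PathLike,
    normalize: bool = True,
    slice_index: int | None = None,
) -> LoadedImage:
    """Read a grayscale image from PNG/TIFF (or one slice of a NIfTI volume).

    Multi-channel rasters are converted by luminance average.  3-D NIfTI
    volumes require an explicit ``slice_index`` (axial, last axis); there is
    no default middle-slice guess.  With ``normalize=False`` the raw values
    are returned as float64 without rescaling (they must already be in
    [0, 1] to pass validation downstream).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        vol = np.asanyarray(nib.load(path).dataobj)
        if vol.ndim == 3:
            if slice_index is None:
                raise ValidationError(
                    "3-D NIfTI input requires an explicit slice index"
                )
            if not (0 <= slice_index < vol.shape[2]):
                raise ValidationError(
                    f"slice index {slice_index} out of range for volume "
                    f"with {vol.shape[2]} slices"
                )
            raw = vol[:, :, slice_index]
        elif vol.ndim == 2:
            raw = vol
        else:
            raise ValidationError(f"unsupported NIfTI ndim={vol.ndim}")
        source_dtype = raw.dtype
    else:
        try:
            raw = iio.imread(path)
        except Exception as exc:  # codec errors become I/O errors
            raise IOError(f"cannot decode image file {path}: {exc}") from exc
        source_dtype = raw.dtype
        raw = _to_single_channel(raw)
    raw = np.asarray(raw)
    if raw.ndim != 2:
        raise ValidationError(
            f"{path} does not decode to a 2-D single-channel raster "
            f"(shape {raw.shape})"
        )
    if normalize:
        values, depth = normalize_to_unit(raw, source_dtype=source_dtype)
    else:
        values = raw.astype(np.float64)
        depth = (
            str(np.iinfo(source_dtype).bits)
            if np.issubdtype(source_dtype, np.integer)
            else "float"
        )
    values = validate_image(values, name=path)
    return LoadedImage(values=values, source_depth=depth)


def write_image(img: np.ndarray, path: str | os.PathLike, depth: int = 8) -> None:
    """Write an image in [0, 1] as an 8- or 16-bit raster.

    Values are clipped to [0, 1], scaled to ``2**depth - 1`` and rounded
    half-up (so 0.5 at depth 8 becomes 128), which keeps fixtures bit-exact.
    The format follows the file extension.
    """
    if depth not in (8, 16):
        raise ValidationError(f"depth must be 8 or 16, got {depth}")
    arr = validate_image(np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0))
    scale = float(2**depth - 1)
    quantized = np.floor(arr * scale + 0.5)  # round half-up
    out = quantized.astype(np.uint8 if depth == 8 else np.uint16)
    try:
        iio.imwrite(os.fspath(path), out)
    except Exception as exc:
        raise IOError(f"cannot write image to {path}: {exc}") from exc


def assert_registered_pair(a: np.ndarray, b: np.ndarray) -> None:
    """Enforce the co-registration contract: identical shapes, nothing more."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise RegistrationError(
            f"images are not a registered pair: shapes {a.shape} vs {b.shape}"
        )
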