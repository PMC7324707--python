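"""Deterministic CT/MR-like phantom pairs for tests and demonstrations.

Real CT shows the skull as a thin bright ring over a flat, dim interior;
MR shows the opposite: a dark skull, textured soft tissue at several
intensity levels, and (on T2) lesions as compact bright regions.  The
phantoms emulate exactly those contrasts on a shared geometry, so the two
images are co-registered by construction and every pipeline stage has a
predictable, hand-checkable response:

* the CT ring is the unique high-saliency structure of the CT image;
* the MR lesion is the unique high-saliency structure of the MR image;
* the MR interior carries the texture/structure the variational stage is
  supposed to transfer.

Texture is Gaussian-smoothed seeded noise with an amplitude small
relative to the tissue-level gaps, so Otsu thresholding of the saliency
maps provably isolates the ring and lesion modes.  Everything is
deterministic given the spec (the seed fixes the texture).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ValidationError

__all__ = ["PhantomSpec", "make_ct_phantom", "make_mr_phantom", "make_pair"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity parameters of a phantom pair.

    Radii are fractions of the image side; intensities are in [0, 1].
    The default size is 128 so full-pipeline tests stay fast; 256 matches
    typical atlas slices.
    """

    size: int = 128
    ring_radius_frac: float = 0.40
    ring_width_frac: float = 0.05
    ring_level: float = 0.95
    tissue_levels: tuple[float, ...] = (0.30, 0.45, 0.60)
    texture_amplitude: float = 0.03
    lesion_center: tuple[float, float] = (0.60, 0.58)
    lesion_radius_frac: float = 0.09
    lesion_level: float = 0.95
    ct_interior_dim: float = 0.5
    background_level: float = 0.05
    mr_ring_level: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.size < 16:
            raise ValidationError(f"size must be >= 16, got {self.size}")
        for name in ("ring_radius_frac", "ring_width_frac", "lesion_radius_frac"):
            v = getattr(self, name)
            if not (0.0 < v < 0.5):
                raise ValidationError(f"{name} must be in (0, 0.5), got {v}")
        levels = (
            (self.ring_level, self.lesion_level, self.background_level,
             self.mr_ring_level, self.texture_amplitude)
            + tuple(self.tissue_levels)
        )
        for v in levels:
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"intensity {v} outside [0, 1]")
        if len(self.tissue_levels) == 0:
            raise ValidationError("at least one tissue level is required")


def _radius_grid(size: int) -> np.ndarray:
    center = (size - 1) / 2.0
    rows, cols = np.mgrid[0:size, 0:size]
    return np.sqrt((rows - center) ** 2 + (cols - center) ** 2)


def _masks(spec: PhantomSpec):
    size = spec.size
    r = _radius_grid(size)
    r_outer = spec.ring_radius_frac * size
    r_inner = r_outer - spec.ring_width_frac * size
    ring = (r <= r_outer) & (r > r_inner)
    interior = r <= r_inner
    rows, cols = np.mgrid[0:size, 0:size]
    lr, lc = spec.lesion_center[0] * size, spec.lesion_center[1] * size
    lesion = (
        np.sqrt((rows - lr) ** 2 + (cols - lc) ** 2) <= spec.lesion_radius_frac * size
    ) & interior
    return ring, interior, lesion


def _tissue_labels(spec: PhantomSpec, interior: np.ndarray) -> np.ndarray:
    """Concentric tissue bands inside the skull, labeled 1..k (0 outside)."""
    r = _radius_grid(spec.size)
    r_inner = (spec.ring_radius_frac - spec.ring_width_frac) * spec.size
    k = len(spec.tissue_levels)
    band = np.minimum((r / max(r_inner, 1e-9) * k).astype(int), k - 1)
    labels = np.where(interior, band + 1, 0)
    return labels


def make_ct_phantom(spec: PhantomSpec | None = None) -> np.ndarray:
    """CT-like image: bright thin ring, flat dim interior, dark exterior."""
    spec = spec or PhantomSpec()
    spec.validate()
    ring, interior, _ = _masks(spec)
    img = np.full((spec.size, spec.size), spec.background_level)
    img[interior] = spec.tissue_levels[0] * spec.ct_interior_dim
    img[ring] = spec.ring_level
    return np.clip(img, 0.0, 1.0)


def make_mr_phantom(spec: PhantomSpec | None = None) -> np.ndarray:
    """MR-like image: dark ring, textured tissue bands, bright lesion."""
    spec = spec or PhantomSpec()
    spec.validate()
    ring, interior, lesion = _masks(spec)
    labels = _tissue_labels(spec, interior)
    img = np.full((spec.size, spec.size), spec.background_level)
    for i, level in enumerate(spec.tissue_levels):
        img[labels == i + 1] = level
    if spec.texture_amplitude > 0:
        rng = np.random.default_rng(spec.seed)
        noise = gaussian_filter(rng.standard_normal(img.shape), sigma=2.0)
        peak = np.abs(noise).max()
        if peak > 0:
            noise = noise / peak * spec.texture_amplitude
        img = np.where(interior, img + noise, img)
    img[ring] = spec.mr_ring_level
    img[lesion] = spec.lesion_level
    return np.clip(img, 0.0, 1.0)


@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth masks of the constructed structures."""

    ring: np.ndarray
    lesion: np.ndarray
    tissue_labels: np.ndarray


def make_pair(
    spec: PhantomSpec | None = None,
) -> tuple[np.ndarray, np.ndarray, PhantomTruth]:
    """Co-registered (ct, mr) pair plus ground-truth masks.

    The ring and lesion masks are disjoint by construction (the lesion
    lives strictly inside the skull).
    """
    spec = spec or PhantomSpec()
    spec.validate()
    ring, interior, lesion = _masks(spec)
    ct = make_ct_phantom(spec)
    mr = make_mr_phantom(spec)
    truth = PhantomTruth(
        ring=ring, lesion=lesion, tissue_labels=_tissue_labels(spec, interior)
    )
    return ct, mr, truth
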