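"""Stage 1: feature-weighted fusion of a registered CT/MR pair.

The weight of each modality at a pixel is decided by two features:

* a binary saliency mask per image (high-intensity structures — skull on
  CT, bright lesions on MR), and
* normalized structure weights STw1, STw2 = mA/(mA+mB), mB/(mA+mB) from
  the structure-feature maps.

Where exactly one image is salient it wins outright (weight 1); elsewhere
the structure weights decide.  The default ``symmetric`` mode keeps
w1 + w2 = 1 everywhere (a true partition of unity, so the fused value is
always between the two inputs); the ``literal`` mode reproduces the
published branch table verbatim, which is not a partition in two of its
regions and is kept only for auditability.

The initial fused image is the pointwise weighted average
F0 = w1*ct + w2*mr, which stage 2 (the variational solver) then refines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import ValidationError
from .image_io import assert_registered_pair, validate_image
from .saliency import binarize_saliency, histogram_saliency
from .structure_tensor import StructureFeatureMap, structure_feature_map

__all__ = [
    "WeightPair",
    "normalize_structure_weights",
    "build_weight_maps",
    "weighted_average",
    "initial_fusion",
]


@dataclass(frozen=True)
class WeightPair:
    """Per-pixel fusion weights in [0, 1]; w1 + w2 = 1 in symmetric mode."""

    w1: np.ndarray
    w2: np.ndarray
    mode: str = "symmetric"


def normalize_structure_weights(
    st_a: StructureFeatureMap | np.ndarray,
    st_b: StructureFeatureMap | np.ndarray,
    eps: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise normalization of two structure-feature maps to sum 1.

    Where both features are (numerically) zero — flat regions in both
    images — the split is 0.5/0.5, the only symmetric choice.
    """
    ma = np.asarray(st_a, dtype=np.float64)
    mb = np.asarray(st_b, dtype=np.float64)
    if ma.shape != mb.shape:
        raise ValidationError(
            f"structure maps must share a shape: {ma.shape} vs {mb.shape}"
        )
    total = ma + mb
    degenerate = total < eps
    safe_total = np.where(degenerate, 1.0, total)
    stw1 = np.where(degenerate, 0.5, ma / safe_total)
    stw2 = np.where(degenerate, 0.5, mb / safe_total)
    return stw1, stw2


def build_weight_maps(
    sw1: np.ndarray,
    sw2: np.ndarray,
    stw1: np.ndarray,
    stw2: np.ndarray,
    mode: str = "symmetric",
) -> WeightPair:
    """Combine saliency masks and structure weights into final weights.

    ``symmetric`` (default): w1 = 1 where only image 1 is salient, 0 where
    only image 2 is salient, and the structure weight otherwise (both or
    neither salient); w2 = 1 - w1.

    ``literal``: the published branch table verbatim — w1 = 1 where both
    masks are nonzero, 0 where only mask 2 is nonzero, stw1 otherwise; w2
    symmetric in the labels — with no renormalization, so w1 + w2 can
    reach 1 + stw2 where both are salient.
    """
    sw1 = np.asarray(sw1, dtype=np.float64)
    sw2 = np.asarray(sw2, dtype=np.float64)
    stw1 = np.asarray(stw1, dtype=np.float64)
    stw2 = np.asarray(stw2, dtype=np.float64)
    shapes = {sw1.shape, sw2.shape, stw1.shape, stw2.shape}
    if len(shapes) != 1:
        raise ValidationError(f"weight inputs must share a shape, got {shapes}")
    a = sw1 != 0
    b = sw2 != 0
    if mode == "symmetric":
        w1 = np.where(a & ~b, 1.0, np.where(~a & b, 0.0, stw1))
        w2 = 1.0 - w1
    elif mode == "literal":
        w1 = np.where(a & b, 1.0, np.where(~a & b, 0.0, stw1))
        w2 = np.where(b & ~a, 1.0, np.where(~b & a, 0.0, stw2))
    else:
        raise ValidationError(f"unknown weight mode: {mode!r}")
    return WeightPair(w1=w1, w2=w2, mode=mode)


def weighted_average(a: np.ndarray, b: np.ndarray, w: WeightPair) -> np.ndarray:
    """Pointwise weighted average F0 = w1*a + w2*b, clipped to [0, 1]."""
    a = validate_image(a, "first image")
    b = validate_image(b, "second image")
    assert_registered_pair(a, b)
    assert_registered_pair(a, w.w1)
    return np.clip(w.w1 * a + w.w2 * b, 0.0, 1.0)


@dataclass
class FusionDiagnostics:
    """All intermediate maps of the weighted-fusion stage."""

    saliency_a: np.ndarray = None
    saliency_b: np.ndarray = None
    mask_a: np.ndarray = None
    mask_b: np.ndarray = None
    structure_a: np.ndarray = None
    structure_b: np.ndarray = None
    stw1: np.ndarray = None
    stw2: np.ndarray = None
    extras: dict[str, Any] = field(default_factory=dict)


def initial_fusion(
    ct: np.ndarray,
    mr: np.ndarray,
    levels: int = 256,
    threshold_method: str = "otsu",
    threshold_fraction: float = 0.5,
    alpha_st: float = 0.5,
    rho: float = 1.0,
    mode: str = "symmetric",
    eps: float = 1e-12,
) -> tuple[np.ndarray, WeightPair, FusionDiagnostics]:
    """Full stage-1 pipeline: saliency + structure features -> F0.

    Returns the initial fused image, the weight maps, and diagnostics
    carrying every intermediate map (saliency, masks, structure features,
    normalized structure weights).
    """
    ct = validate_image(ct, "ct")
    mr = validate_image(mr, "mr")
    assert_registered_pair(ct, mr)
    sal_a = histogram_saliency(ct, levels)
    sal_b = histogram_saliency(mr, levels)
    mask_a = binarize_saliency(sal_a, threshold_method, threshold_fraction)
    mask_b = binarize_saliency(sal_b, threshold_method, threshold_fraction)
    st_a = structure_feature_map(ct, alpha_st=alpha_st, rho=rho)
    st_b = structure_feature_map(mr, alpha_st=alpha_st, rho=rho)
    stw1, stw2 = normalize_structure_weights(st_a, st_b, eps=eps)
    weights = build_weight_maps(mask_a, mask_b, stw1, stw2, mode=mode)
    fused = weighted_average(ct, mr, weights)
    diag = FusionDiagnostics(
        saliency_a=sal_a.values,
        saliency_b=sal_b.values,
        mask_a=mask_a,
        mask_b=mask_b,
        structure_a=st_a.magnitude,
        structure_b=st_b.magnitude,
        stw1=stw1,
        stw2=stw2,
    )
    return fused, weights, diag
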