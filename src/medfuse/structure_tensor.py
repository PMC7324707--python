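"""Per-pixel structure tensors and the scalar structure-feature map.

The structure tensor G = (smoothed) outer product of the image gradient is
a symmetric positive-semidefinite 2x2 matrix per pixel.  Its eigenvalues
lambda1 >= lambda2 >= 0 are the maximal and minimal local contrast-change
rates, and the leading eigenvector theta1 the dominant gradient direction.
The scalar feature

    m = (lambda1 + lambda2)/2 + alpha * (lambda1 - lambda2)/2

blends total local contrast (the trace term) with anisotropy, so both
strong edges and textured regions respond; it is nonnegative by
construction and feeds the structure-weight normalization of the fusion
stage.

Gradients are forward differences with replicate (Neumann) boundary — the
same discretization the variational solver uses, so the feature and the
regularizer see identical edge geometry.  Component 0 of a gradient field
is the horizontal derivative (along columns), component 1 the vertical
(along rows).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ValidationError
from .image_io import validate_image

__all__ = [
    "TensorField",
    "StructureFeatureMap",
    "discrete_gradient",
    "structure_tensor_field",
    "structure_feature_map",
]


def discrete_gradient(img: np.ndarray) -> np.ndarray:
    """Forward-difference gradient with Neumann boundary.

    Returns an array of shape (2, H, W): ``grad[0]`` is the horizontal
    component I(r, c+1) - I(r, c) (zero in the last column), ``grad[1]``
    the vertical component I(r+1, c) - I(r, c) (zero in the last row).
    """
    u = np.asarray(img, dtype=np.float64)
    if u.ndim != 2:
        raise ValidationError(f"expected a 2-D image, got ndim={u.ndim}")
    grad = np.zeros((2,) + u.shape, dtype=np.float64)
    grad[0, :, :-1] = u[:, 1:] - u[:, :-1]
    grad[1, :-1, :] = u[1:, :] - u[:-1, :]
    return grad


@dataclass(frozen=True)
class TensorField:
    """Per-pixel symmetric 2x2 structure tensor with its eigensystem.

    ``g11``/``g12``/``g22`` are the tensor components (g11 pairs with the
    horizontal gradient component), ``lam1 >= lam2`` the eigenvalues, and
    ``theta1``/``theta2`` the unit eigenvectors, each of shape (2, H, W).
    """

    g11: np.ndarray
    g12: np.ndarray
    g22: np.ndarray
    lam1: np.ndarray
    lam2: np.ndarray
    theta1: np.ndarray
    theta2: np.ndarray

    @property
    def shape(self):
        return self.g11.shape


def _eigen_2x2_symmetric(g11, g12, g22):
    """Closed-form eigensystem of a field of symmetric 2x2 matrices."""
    half_trace = 0.5 * (g11 + g22)
    half_gap = 0.5 * (g11 - g22)
    root = np.sqrt(half_gap**2 + g12**2)
    lam1 = half_trace + root
    lam2 = half_trace - root
    # Leading eigenvector: (g12, lam1 - g11) unless the off-diagonal
    # vanishes, in which case the tensor is already diagonal.
    v1 = np.where(g12 != 0.0, g12, np.where(g11 >= g22, 1.0, 0.0))
    v2 = np.where(g12 != 0.0, lam1 - g11, np.where(g11 >= g22, 0.0, 1.0))
    norm = np.sqrt(v1**2 + v2**2)
    # A zero norm only occurs for g12=0 handled above, but guard anyway.
    norm = np.where(norm == 0.0, 1.0, norm)
    theta1 = np.stack([v1 / norm, v2 / norm])
    theta2 = np.stack([-theta1[1], theta1[0]])
    return lam1, lam2, theta1, theta2


def structure_tensor_field(img: np.ndarray, rho: float = 1.0) -> TensorField:
    """Structure tensor of an image, optionally Gaussian-smoothed.

    With ``rho = 0`` the tensor is the raw per-pixel outer product of the
    forward-difference gradient (rank <= 1); with ``rho > 0`` each
    component is convolved with a Gaussian of standard deviation ``rho``
    pixels (replicate boundary), which pools gradient orientation over a
    neighborhood and makes corners/texture distinguishable from edges.
    """
    if rho < 0:
        raise ValidationError(f"rho must be >= 0, got {rho}")
    arr = validate_image(img)
    gx, gy = discrete_gradient(arr)
    g11 = gx * gx
    g12 = gx * gy
    g22 = gy * gy
    if rho > 0:
        g11 = gaussian_filter(g11, sigma=rho, mode="nearest")
        g12 = gaussian_filter(g12, sigma=rho, mode="nearest")
        g22 = gaussian_filter(g22, sigma=rho, mode="nearest")
    lam1, lam2, theta1, theta2 = _eigen_2x2_symmetric(g11, g12, g22)
    return TensorField(
        g11=g11, g12=g12, g22=g22,
        lam1=lam1, lam2=lam2, theta1=theta1, theta2=theta2,
    )


@dataclass(frozen=True)
class StructureFeatureMap:
    """Nonnegative scalar structure feature plus the dominant direction."""

    magnitude: np.ndarray
    direction: np.ndarray  # theta1, shape (2, H, W)

    def __array__(self, dtype=None, copy=None):
        if dtype is None:
            return self.magnitude
        return self.magnitude.astype(dtype)

    @property
    def shape(self):
        return self.magnitude.shape


def structure_feature_map(
    img: np.ndarray, alpha_st: float = 0.5, rho: float = 1.0
) -> StructureFeatureMap:
    """Scalar structure feature m = (l1+l2)/2 + alpha_st*(l1-l2)/2.

    ``alpha_st = 0`` gives the mean eigenvalue (total contrast energy),
    ``alpha_st = 1`` gives lambda1 (the maximal contrast-change rate);
    intermediate values weight anisotropy in between.  The feature scales
    quadratically with image intensity (it is built from squared
    gradients).
    """
    if alpha_st < 0:
        raise ValidationError(f"alpha_st must be >= 0, got {alpha_st}")
    field = structure_tensor_field(img, rho=rho)
    m = 0.5 * (field.lam1 + field.lam2) + alpha_st * 0.5 * (field.lam1 - field.lam2)
    # eigenvalues of a smoothed PSD field can round to tiny negatives
    m = np.maximum(m, 0.0)
    return StructureFeatureMap(magnitude=m, direction=field.theta1)
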