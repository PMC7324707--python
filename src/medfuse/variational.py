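"""Stage 2: variational refinement by a primal-dual (Chambolle-Pock) solver.

The fused image u minimizes the convex energy

    E(u) = (alpha/2) * sum (u - F0)^2  +  sum |grad u - grad I_mr|

where F0 is the stage-1 weighted fusion, I_mr the MR image, and |.| the
per-pixel Euclidean norm of the 2-vector.  The fidelity term anchors the
intensities (bone, lesions) extracted in stage 1; the L1 gradient term is
a total-variation-type regularizer that pulls the fused gradient field
toward the MR gradients, transferring soft-tissue texture while keeping
the result piecewise smooth.

The saddle-point form max_{|p|<=1} <grad u - grad mr, p> of the L1 term
gives the iteration (starting from u0 = F0, p0 = 0, ubar0 = u0):

    p    <- proj_{|p|<=1} ( p + sigma * (grad ubar - grad mr) )
    u+   <- ( u + tau * div p + alpha*tau*F0 ) / (1 + alpha*tau)
    ubar <- 2 u+ - u ;  u <- u+

convergent when sigma * tau * ||grad||^2 <= 1 with ||grad||^2 <= 8 for
the forward-difference gradient.  The divergence is the exact negative
adjoint of the gradient, so <grad u, p> = -<u, div p> holds to rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .errors import SolverError, ValidationError
from .image_io import assert_registered_pair, validate_image
from .structure_tensor import discrete_gradient

__all__ = [
    "SolverConfig",
    "SolverTrace",
    "discrete_divergence",
    "fusion_energy",
    "project_dual",
    "primal_dual_solve",
]

GRAD_OPERATOR_NORM_SQ = 8.0  # forward differences on a 2-D grid


@dataclass(frozen=True)
class SolverConfig:
    """Parameters of the primal-dual iteration.

    ``alpha_fid`` is the fidelity weight (larger pins u to F0 harder),
    ``sigma``/``tau`` the dual/primal step sizes (stable when
    sigma*tau*8 <= 1), ``max_iter`` the iteration cap and ``tol`` the
    relative-primal-change stopping tolerance.
    """

    alpha_fid: float = 8.0
    sigma: float = 0.35
    tau: float = 0.35
    max_iter: int = 300
    tol: float = 1e-5

    def validate(self) -> None:
        if self.alpha_fid <= 0:
            raise ValidationError(f"alpha_fid must be > 0, got {self.alpha_fid}")
        if self.sigma <= 0 or self.tau <= 0:
            raise ValidationError(
                f"sigma and tau must be > 0, got sigma={self.sigma}, tau={self.tau}"
            )
        if self.sigma * self.tau * GRAD_OPERATOR_NORM_SQ > 1.0 + 1e-12:
            raise ValidationError(
                "step sizes violate stability: sigma*tau*8 = "
                f"{self.sigma * self.tau * GRAD_OPERATOR_NORM_SQ:.6g} > 1"
            )
        if self.max_iter < 0:
            raise ValidationError(f"max_iter must be >= 0, got {self.max_iter}")
        if self.tol < 0:
            raise ValidationError(f"tol must be >= 0, got {self.tol}")


@dataclass
class SolverTrace:
    """Per-iteration primal energies and relative changes."""

    energies: list[float] = dataclass_field(default_factory=list)
    rel_changes: list[float] = dataclass_field(default_factory=list)
    iterations_run: int = 0


def discrete_divergence(p: np.ndarray) -> np.ndarray:
    """Divergence of a dual field, the exact negative gradient adjoint.

    ``p`` has shape (2, H, W) with p[0] the horizontal and p[1] the
    vertical component.  Backward differences with the boundary rule that
    makes <grad u, p> = -<u, div p> hold exactly for the Neumann
    forward-difference gradient.
    """
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 3 or p.shape[0] != 2:
        raise ValidationError(f"dual field must have shape (2, H, W), got {p.shape}")
    div = np.zeros(p.shape[1:], dtype=np.float64)
    # horizontal component: d/dx adjoint (last column of p[0] is inert)
    div[:, 0] += p[0, :, 0]
    div[:, 1:-1] += p[0, :, 1:-1] - p[0, :, :-2]
    div[:, -1] += -p[0, :, -2]
    # vertical component
    div[0, :] += p[1, 0, :]
    div[1:-1, :] += p[1, 1:-1, :] - p[1, :-2, :]
    div[-1, :] += -p[1, -2, :]
    return div


def fusion_energy(
    u: np.ndarray, f0: np.ndarray, mr: np.ndarray, alpha_fid: float
) -> float:
    """Discrete fusion energy (alpha/2)*sum (u-F0)^2 + sum |grad u - grad mr|."""
    u = np.asarray(u, dtype=np.float64)
    f0 = np.asarray(f0, dtype=np.float64)
    mr = np.asarray(mr, dtype=np.float64)
    if not (u.shape == f0.shape == mr.shape):
        raise ValidationError(
            f"shape mismatch: u {u.shape}, F0 {f0.shape}, mr {mr.shape}"
        )
    fidelity = 0.5 * alpha_fid * float(np.sum((u - f0) ** 2))
    diff = discrete_gradient(u) - discrete_gradient(mr)
    regularizer = float(np.sum(np.sqrt(diff[0] ** 2 + diff[1] ** 2)))
    return fidelity + regularizer


def project_dual(p_tilde: np.ndarray) -> np.ndarray:
    """Project a dual field onto the pointwise Euclidean unit ball.

    p = p~ / max(1, |p~|) per pixel; idempotent, identity inside the ball.
    """
    p_tilde = np.asarray(p_tilde, dtype=np.float64)
    norm = np.sqrt(p_tilde[0] ** 2 + p_tilde[1] ** 2)
    return p_tilde / np.maximum(1.0, norm)[None, :, :]


def primal_dual_solve(
    f0: np.ndarray,
    mr: np.ndarray,
    cfg: SolverConfig | None = None,
) -> tuple[np.ndarray, SolverTrace]:
    """Minimize the fusion energy by the extrapolated primal-dual iteration.

    Starts from u = F0 (the data term's minimizer) and a zero dual field.
    Stops at ``cfg.max_iter`` or when the relative primal change
    ||u_{t+1} - u_t||_2 / ||u_t||_2 drops below ``cfg.tol``.  Returns the
    solution clipped to [0, 1] (clipping happens once, after the last
    iteration, to preserve the adjoint structure inside the loop) and the
    energy trace.
    """
    cfg = cfg or SolverConfig()
    cfg.validate()
    f0 = validate_image(f0, "F0")
    mr = validate_image(mr, "mr")
    assert_registered_pair(f0, mr)

    u = f0.copy()
    u_bar = u.copy()
    p = np.zeros((2,) + u.shape, dtype=np.float64)
    grad_mr = discrete_gradient(mr)
    trace = SolverTrace()
    atau = cfg.alpha_fid * cfg.tau

    for t in range(cfg.max_iter):
        p = project_dual(p + cfg.sigma * (discrete_gradient(u_bar) - grad_mr))
        u_next = (u + cfg.tau * discrete_divergence(p) + atau * f0) / (1.0 + atau)
        if not np.all(np.isfinite(u_next)):
            raise SolverError(f"non-finite iterate at iteration {t}")
        u_bar = 2.0 * u_next - u
        denom = np.linalg.norm(u)
        rel = np.linalg.norm(u_next - u) / max(denom, 1e-12)
        u = u_next
        trace.energies.append(fusion_energy(u, f0, mr, cfg.alpha_fid))
        trace.rel_changes.append(rel)
        trace.iterations_run = t + 1
        if rel < cfg.tol:
            break

    return np.clip(u, 0.0, 1.0), trace
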