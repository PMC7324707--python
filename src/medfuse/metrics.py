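"""Objective fusion-quality metrics: SF, fusion MI, Q^AB/F and Q_W.

All four metrics are computed on intensities rescaled to the 0..255 range,
the convention of the fusion-metrics literature, so values are comparable
with published implementations.  Higher is better for every metric.

* ``spatial_frequency`` — RMS of horizontal and vertical neighbor
  differences; a sharpness proxy.
* ``normalized_fusion_mi`` — how much each source image's intensity
  distribution is retained in the fusion, as mutual information
  normalized by entropies; 2 means the fusion is informationally
  equivalent to both sources.
* ``q_abf`` — the Xydeas-Petrovic edge-information transfer measure:
  per-pixel Sobel edge strength and orientation preservation pushed
  through sigmoids and weighted by source edge strength.
* ``q_w`` — Piella's weighted quality index: the universal image quality
  index Q0 between each source and the fusion in sliding windows, blended
  by local variance saliency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import sobel, uniform_filter

from .errors import ValidationError
from .image_io import assert_registered_pair, validate_image
from .saliency import quantize

__all__ = [
    "MetricsReport",
    "spatial_frequency",
    "normalized_fusion_mi",
    "q_abf",
    "q_w",
    "evaluate",
]

# Standard sigmoid constants of the edge-preservation model.
GAMMA_G, KAPPA_G, SIGMA_G = 0.9994, -15.0, 0.5
GAMMA_A, KAPPA_A, SIGMA_A = 0.9879, -22.0, 0.8


@dataclass(frozen=True)
class MetricsReport:
    """Bundle of the four in-scope fusion metrics (VIFF not implemented)."""

    sf: float
    mi: float
    q_abf: float
    q_w: float
    viff: None = None  # defined only by citation in the source method

    def as_dict(self) -> dict:
        return {
            "sf": self.sf,
            "mi": self.mi,
            "q_abf": self.q_abf,
            "q_w": self.q_w,
            "viff": self.viff,
        }


def _to_255(img: np.ndarray) -> np.ndarray:
    return validate_image(img) * 255.0


def spatial_frequency(img: np.ndarray) -> float:
    """SF = sqrt(RF^2 + CF^2) on the 0..255 intensity scale.

    RF is the RMS of horizontal neighbor differences I(r,c) - I(r,c-1)
    over all valid pixels, CF the vertical analog.  A single-row or
    single-column direction with no neighbors contributes 0.
    """
    arr = _to_255(img)
    rf2 = float(np.mean((arr[:, 1:] - arr[:, :-1]) ** 2)) if arr.shape[1] > 1 else 0.0
    cf2 = float(np.mean((arr[1:, :] - arr[:-1, :]) ** 2)) if arr.shape[0] > 1 else 0.0
    return float(np.sqrt(rf2 + cf2))


def _entropy_and_mi(x: np.ndarray, y: np.ndarray, bins: int):
    """Joint-histogram mutual information I(X,Y) and entropies, in bits."""
    joint, _, _ = np.histogram2d(
        x.ravel(), y.ravel(), bins=bins, range=[[0, bins], [0, bins]]
    )
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)

    def _h(p):
        p = p[p > 0]
        return float(-np.sum(p * np.log2(p)))

    hx, hy = _h(px), _h(py)
    hxy = _h(pxy.ravel())
    return hx + hy - hxy, hx, hy


def normalized_fusion_mi(
    a: np.ndarray, b: np.ndarray, f: np.ndarray, bins: int = 256
) -> float:
    """MI^AB_F = 2 * [ I(F,A)/(H(F)+H(A)) + I(F,B)/(H(F)+H(B)) ].

    Intensities are quantized to ``bins`` levels; logs are base 2 with
    0*log 0 := 0.  Degenerate convention: a ratio whose entropies vanish
    is 0.5 when both images are identical constants, else 0.
    """
    if bins < 2:
        raise ValidationError(f"bins must be >= 2, got {bins}")
    qa = quantize(a, bins)
    qb = quantize(b, bins)
    qf = quantize(f, bins)
    assert_registered_pair(qa, qf)
    assert_registered_pair(qb, qf)

    def _term(qx):
        mi, hf, hx = _entropy_and_mi(qf, qx, bins)
        if hf == 0.0 or hx == 0.0:
            both_constant = hf == 0.0 and hx == 0.0
            return 0.5 if both_constant and np.array_equal(qf, qx) else 0.0
        return mi / (hf + hx)

    return 2.0 * (_term(qa) + _term(qb))


def _edge_strength_orientation(img255: np.ndarray):
    """Sobel edge magnitude and orientation folded into (-pi/2, pi/2]."""
    gx = sobel(img255, axis=1, mode="reflect")
    gy = sobel(img255, axis=0, mode="reflect")
    g = np.sqrt(gx**2 + gy**2)
    alpha = np.arctan2(gy, gx)
    alpha = np.where(alpha > np.pi / 2, alpha - np.pi, alpha)
    alpha = np.where(alpha <= -np.pi / 2, alpha + np.pi, alpha)
    return g, alpha


def _edge_preservation(ga, aa, gf, af):
    """Per-pixel edge preservation Q^XF = Qg * Qalpha (sigmoid model)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            ga > gf,
            np.divide(gf, ga, out=np.zeros_like(ga), where=ga > 0),
            np.divide(ga, gf, out=np.zeros_like(ga), where=gf > 0),
        )
    # equal nonzero strengths preserve perfectly; 0/0 stays 0 (zero weight)
    ratio = np.where((ga == gf) & (ga > 0), 1.0, ratio)
    delta = np.abs(np.abs(aa - af) - np.pi / 2) / (np.pi / 2)
    qg = GAMMA_G / (1.0 + np.exp(KAPPA_G * (ratio - SIGMA_G)))
    qa = GAMMA_A / (1.0 + np.exp(KAPPA_A * (delta - SIGMA_A)))
    return qg * qa


def q_abf(a: np.ndarray, b: np.ndarray, f: np.ndarray) -> float:
    """Edge-information transfer Q^AB/F in [0, 1].

    Each source pixel's edge-preservation factor (strength ratio and
    orientation agreement through the standard sigmoids) is weighted by
    that source's own edge strength; the fusion score is the weighted
    mean over both sources and all pixels.  Constant sources (no edges
    anywhere) yield 0 by convention.
    """
    a255, b255, f255 = _to_255(a), _to_255(b), _to_255(f)
    assert_registered_pair(a255, f255)
    assert_registered_pair(b255, f255)
    ga, aa = _edge_strength_orientation(a255)
    gb, ab = _edge_strength_orientation(b255)
    gf, af = _edge_strength_orientation(f255)
    q_af = _edge_preservation(ga, aa, gf, af)
    q_bf = _edge_preservation(gb, ab, gf, af)
    wa, wb = ga, gb
    denom = float(np.sum(wa + wb))
    if denom == 0.0:
        return 0.0
    return float(np.sum(q_af * wa + q_bf * wb) / denom)


def _window_stats(img: np.ndarray, size: int):
    """Mean and variance over every full size x size window (valid part)."""
    r = size // 2
    mean = uniform_filter(img, size=size, mode="constant")[r:-r, r:-r]
    mean_sq = uniform_filter(img**2, size=size, mode="constant")[r:-r, r:-r]
    var = np.maximum(mean_sq - mean**2, 0.0)
    return mean, var


def q_w(a: np.ndarray, b: np.ndarray, f: np.ndarray, window: int = 7) -> float:
    """Piella's weighted fusion quality index Q_W in [0, 1].

    In every sliding window, the universal image quality index Q0 of
    (source, fusion) is computed for both sources and blended by the local
    saliency lambda(w) = var(A|w) / (var(A|w) + var(B|w)); windows are
    themselves weighted by c(w) proportional to max(var(A|w), var(B|w)).
    Q0 can be negative on anticorrelated inputs, so the final value is
    floored at 0 to keep the documented [0, 1] range.
    """
    if window < 3 or window % 2 == 0:
        raise ValidationError(f"window must be odd and >= 3, got {window}")
    a255, b255, f255 = _to_255(a), _to_255(b), _to_255(f)
    assert_registered_pair(a255, f255)
    assert_registered_pair(b255, f255)
    if min(a255.shape) < window:
        raise ValidationError(
            f"images of shape {a255.shape} are smaller than the {window}x{window} window"
        )
    n = window * window
    bessel = n / (n - 1)  # unbiased variance, the Q0 convention

    ma, va = _window_stats(a255, window)
    mb, vb = _window_stats(b255, window)
    mf, vf = _window_stats(f255, window)
    va, vb, vf = va * bessel, vb * bessel, vf * bessel

    def _q0(mx, vx, x255):
        mxy = uniform_filter(x255 * f255, size=window, mode="constant")
        r = window // 2
        cov = (mxy[r:-r, r:-r] - mx * mf) * bessel
        num = 4.0 * cov * mx * mf
        den = (vx + vf) * (mx**2 + mf**2)
        q0 = np.ones_like(num)
        ok = den > 1e-12
        q0[ok] = num[ok] / den[ok]
        # variance-degenerate but luminance-informative windows
        lum_only = (~ok) & (mx**2 + mf**2 > 1e-12)
        q0[lum_only] = 2.0 * mx[lum_only] * mf[lum_only] / (
            mx[lum_only] ** 2 + mf[lum_only] ** 2
        )
        return q0

    q0_af = _q0(ma, va, a255)
    q0_bf = _q0(mb, vb, b255)

    total = va + vb
    lam = np.where(total > 0, np.divide(va, np.where(total > 0, total, 1.0)), 0.5)
    c = np.maximum(va, vb)
    c_sum = float(c.sum())
    if c_sum == 0.0:
        c = np.full_like(c, 1.0 / c.size)
    else:
        c = c / c_sum
    value = float(np.sum(c * (lam * q0_af + (1.0 - lam) * q0_bf)))
    return float(np.clip(value, 0.0, 1.0))


def evaluate(
    a: np.ndarray,
    b: np.ndarray,
    f: np.ndarray,
    bins: int = 256,
    window: int = 7,
) -> MetricsReport:
    """Compute all four in-scope metrics with their default settings."""
    return MetricsReport(
        sf=spatial_frequency(f),
        mi=normalized_fusion_mi(a, b, f, bins=bins),
        q_abf=q_abf(a, b, f),
        q_w=q_w(a, b, f, window=window),
    )
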