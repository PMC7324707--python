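"""Independent brute-force oracles the tests compare the package against.

Each oracle re-derives a quantity from its definition (pairwise sums,
generic eigensolvers, naive loops, subgradient descent) without touching
the code path it checks.
"""

import numpy as np

from medfuse.saliency import quantize
from medfuse.structure_tensor import discrete_gradient
from medfuse.variational import discrete_divergence


def pairwise_saliency(img, levels=256):
    """Per-pixel mean absolute intensity distance to all pixels, O(N^2)."""
    q = quantize(img, levels).astype(np.float64).ravel()
    sal = np.abs(q[:, None] - q[None, :]).mean(axis=1)
    return sal.reshape(np.asarray(img).shape)


def eigenvalues_generic(g11, g12, g22):
    """Per-pixel eigenvalues via the generic symmetric eigensolver."""
    mats = np.stack(
        [np.stack([g11, g12], axis=-1), np.stack([g12, g22], axis=-1)], axis=-2
    )
    vals = np.linalg.eigvalsh(mats)  # ascending
    return vals[..., 1], vals[..., 0]


def naive_energy(u, f0, mr, alpha):
    """Term-by-term recomputation of the fusion energy with python loops."""
    u = np.asarray(u, float)
    f0 = np.asarray(f0, float)
    mr = np.asarray(mr, float)
    h, w = u.shape
    fid = 0.0
    for r in range(h):
        for c in range(w):
            fid += (u[r, c] - f0[r, c]) ** 2
    fid *= 0.5 * alpha
    reg = 0.0
    for r in range(h):
        for c in range(w):
            dux = (u[r, c + 1] - u[r, c]) if c < w - 1 else 0.0
            duy = (u[r + 1, c] - u[r, c]) if r < h - 1 else 0.0
            dmx = (mr[r, c + 1] - mr[r, c]) if c < w - 1 else 0.0
            dmy = (mr[r + 1, c] - mr[r, c]) if r < h - 1 else 0.0
            reg += np.sqrt((dux - dmx) ** 2 + (duy - dmy) ** 2)
    return fid + reg


def subgradient_solve(f0, mr, alpha, iters=4000, step0=0.05):
    """Projected subgradient descent on the fusion energy; returns best energy.

    Diminishing steps step0/sqrt(t+1), iterates projected onto [0,1];
    tracks the best energy seen (the subgradient method is not monotone).
    """
    from medfuse.variational import fusion_energy

    u = np.asarray(f0, float).copy()
    grad_mr = discrete_gradient(mr)
    best = fusion_energy(u, f0, mr, alpha)
    for t in range(iters):
        v = discrete_gradient(u) - grad_mr
        norm = np.sqrt(v[0] ** 2 + v[1] ** 2)
        direction = np.where(norm > 0, v / np.where(norm > 0, norm, 1.0), 0.0)
        g = alpha * (u - f0) - discrete_divergence(direction)
        u = np.clip(u - step0 / np.sqrt(t + 1.0) * g, 0.0, 1.0)
        e = fusion_energy(u, f0, mr, alpha)
        if e < best:
            best = e
    return best


def mi_by_counting(a_levels, b_levels, bins):
    """Mutual information in bits from a dict-of-counts joint histogram."""
    from collections import Counter

    pairs = Counter(zip(a_levels.ravel().tolist(), b_levels.ravel().tolist()))
    n = a_levels.size
    pa = Counter(a_levels.ravel().tolist())
    pb = Counter(b_levels.ravel().tolist())
    mi = 0.0
    for (x, y), cnt in pairs.items():
        pxy = cnt / n
        mi += pxy * np.log2(pxy / ((pa[x] / n) * (pb[y] / n)))
    ha = -sum((c / n) * np.log2(c / n) for c in pa.values())
    hb = -sum((c / n) * np.log2(c / n) for c in pb.values())
    return mi, ha, hb
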