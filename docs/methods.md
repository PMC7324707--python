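# Methods

## Model

Given a co-registered pair of grayscale images — a CT slice `I_ct` and an
MR slice `I_mr`, both mapped to [0,1] — the fused image is produced in
two stages.

### Stage 1: feature-weighted fusion

Two complementary features drive the per-pixel weights.

**Saliency.** The global-contrast saliency of a pixel is its mean
absolute intensity distance to all pixels of the image. Because the
distance depends only on intensity, the O(N²) pairwise sum collapses to a
sum over the histogram: after quantizing to `levels` bins (default 256,
matching 8-bit sources; quantization is `floor(v·(levels−0.001))`),

    S(c_l) = Σ_j f_j · |c_l − c_j|,

with `f_j` the empirical frequency of level `c_j`. S is reported on the
integer level scale and not renormalized: only its relative magnitude
matters. The map is thresholded into a binary mask of high-intensity
structures; the default threshold is Otsu's (parameter-free and
deterministic), with a `fraction`-of-maximum alternative. Pixels strictly
above the threshold are salient; an all-constant saliency map yields an
empty mask rather than an error.

**Structure.** The structure tensor is the Gaussian-smoothed outer
product of the image gradient (forward differences, replicate boundary;
smoothing scale `rho`, default 1.0 px — `rho = 0` gives the raw rank-1
tensor). Its eigenvalues λ1 ≥ λ2 ≥ 0 are the maximal/minimal local
contrast-change rates; the scalar feature

    m = (λ1 + λ2)/2 + α_st (λ1 − λ2)/2,   α_st ∈ [0, 1] (default 0.5)

blends total contrast energy with anisotropy. The published formula for
this feature is ambiguous as printed (it mixes the leading eigenvector
into what must be a nonnegative scalar for the weight normalization to
make sense); this package defines the feature as the trace/anisotropy
blend above — nonnegative by construction, reducing to λ1 at α_st = 1 and
to the mean eigenvalue at α_st = 0 — and carries the leading eigenvector
separately for diagnostics. No value of α_st is prescribed by the source
method; 0.5 weights both terms equally.

**Weights.** With binary masks `Sw1`, `Sw2` and normalized structure
weights `STw1 = m_ct/(m_ct+m_mr)` (0.5/0.5 where the denominator is below
`eps`), the default `symmetric` mode sets

    w1 = 1      where Sw1=1 and Sw2=0       (CT-exclusive saliency)
    w1 = 0      where Sw1=0 and Sw2=1       (MR-exclusive saliency)
    w1 = STw1   otherwise (both or neither salient),   w2 = 1 − w1.

This is a partition of unity, so `F0 = w1·I_ct + w2·I_mr` always lies
between the two inputs. The branch table as published is asymmetric and
sums to more than 1 where both images are salient; it is preserved
verbatim behind `weight_mode="literal"` for auditability, documented as a
non-partition. In the both-salient overlap the symmetric mode falls back
to structure weights — the only data-driven tie-break already defined —
rather than preferring either modality.

### Stage 2: variational refinement

F0 preserves high-intensity structures but can blur tissue texture. The
final image minimizes the convex energy

    E(u) = (α/2) Σ_x (u − F0)² + Σ_x |(∇u − ∇I_mr)(x)|₂,

the discrete sums running over pixels. The MR image is the gradient
target because soft-tissue contrast lives there. The L1 term is handled
through its dual: E is the saddle-point problem
`min_u max_{|p(x)|≤1} (α/2)‖u−F0‖² + ⟨∇u − ∇I_mr, p⟩`, and the solver is
the extrapolated first-order primal–dual iteration

    p ← proj_{|p|≤1}( p + σ(∇ū − ∇I_mr) )
    u⁺ ← ( u + τ div p + ατ F0 ) / (1 + ατ)
    ū ← 2u⁺ − u;  u ← u⁺

with u⁰ = ū⁰ = F0 (the fidelity term's minimizer — a warm start) and
p⁰ = 0. The relaxation line of the published algorithm literally
overwrites the primal iterate with the extrapolation, which diverges for
the quadratic term; here the extrapolated point feeds only the next dual
update, the standard convergent form. The dual constraint is isotropic
(per-pixel Euclidean ball), matching the printed projection
`p̃/max(1, |p̃|)`.

Discretization: forward differences with Neumann (replicate) boundary for
the gradient; the divergence is its exact negative adjoint (backward
differences with the matching boundary rule), so `⟨∇u, p⟩ = −⟨u, div p⟩`
holds to rounding — the tests assert 1e−10.

## Parameters

| name | default | meaning |
|---|---|---|
| `levels` | 256 | saliency quantization bins (8-bit scale) |
| `threshold_method` | `otsu` | saliency binarization (`fraction` alternative) |
| `alpha_st` | 0.5 | anisotropy weight of the structure feature (unitless) |
| `rho` | 1.0 px | Gaussian scale of tensor smoothing |
| `weight_mode` | `symmetric` | partition-of-unity weights (`literal` = printed table) |
| `alpha_fid` | 8.0 | fidelity weight α; larger pins u to F0 (∞ ⇒ u = F0) |
| `sigma`, `tau` | 0.35 | dual/primal steps; στ·8 = 0.98 ≤ 1 (stability bound) |
| `max_iter` | 300 | iteration cap; `0` returns F0 unchanged |
| `tol` | 1e−5 | stop when ‖u⁺−u‖₂/‖u‖₂ falls below |
| `mi_bins` | 256 | MI joint-histogram bins |
| `qw_window` | 7 | Q_W sliding-window side (odd) |

The source method publishes none of the solver constants; these defaults
were fixed once from standard practice (steps at the stability boundary,
a fidelity weight that visibly preserves stage-1 intensities while
letting texture transfer, and a tolerance that converges the default
phantom within the cap).

## Numerical choices and degenerate inputs

- Images are float64 in [0,1]; integer rasters scale by `2^depth − 1`,
  float rasters are min/max-normalized (constant float input → zeros).
  Writing rounds half-up, so a 0.5 image at depth 8 is exactly 128.
- Clipping of u to [0,1] happens once, after the final iteration:
  clipping inside the loop would break the gradient/divergence adjoint
  pair the convergence theory needs.
- The primal energy is not monotone: with the dual cold-started at zero
  it rises for roughly the first 15 iterations before descending. The
  final energy is always at or below the energy of F0, and the
  10-iteration moving average of the trace descends after that
  transient; both are under test.
- Eigenpairs of the 2×2 tensors are closed-form; smoothing can push λ2 a
  rounding error below zero, so the structure feature is floored at 0.
- Degenerate metric conventions: MI ratios with a zero entropy are 0.5
  for identical constant images and 0 otherwise; Q_W windows with zero
  variance fall back to the luminance term of Q0 (1 for identical
  constants); Q^AB/F of edge-free (constant) sources is 0; Q_W is floored
  at 0 (Q0 ∈ [−1,1] can make the raw blend negative on adversarial
  anticorrelated inputs, outside the index's documented [0,1] range).
- The MI estimator carries the usual finite-sample bias
  ≈ (bins−1)²/(2N ln 2) bits: at 256 bins and a 256×256 image,
  independent noise scores ≈ 0.2 rather than 0. Tests of the
  independence limit therefore use 64 bins, where the bias is
  negligible, plus a shrink-with-N check at default bins.
- Q^AB/F uses the standard sigmoid parameterization (Γ_g = 0.9994,
  κ_g = −15, σ_g = 0.5; Γ_α = 0.9879, κ_α = −22, σ_α = 0.8) with Sobel
  gradients. Under these constants the metric's self-fusion ceiling is
  Qg(1)·Qα(1) ≈ 0.9748, not 1; the tests pin that exact closed-form
  value.

## Phantoms: what they emulate, and what they do not

`medfuse.phantoms` builds deterministic 128×128 (configurable)
co-registered pairs: the CT phantom has a bright thin "skull" ring
(0.95) over a flat dim interior and dark exterior; the MR phantom shares
the geometry with a dark ring (0.10), three concentric tissue bands
(0.30/0.45/0.60) textured by Gaussian-smoothed seeded noise (amplitude
0.03), and a bright "lesion" disc (0.95). Levels were chosen once so
that the ring is the unique Otsu-salient structure of the CT image and
the lesion that of the MR image — the regime the fusion method is
designed for — and ground-truth masks ship with each pair.

The phantoms emulate intensity roles, not anatomy: no partial-volume
effects, noise statistics of real scanners, bias fields, registration
error, or anatomical texture. Passing tests therefore demonstrate the
algorithmic contracts (feature extraction, weight construction, solver
optimality, metric identities) — not clinical image quality, which the
source method assessed on real atlas slices that are not redistributable
here.

## Known limitations

- 2-D single-channel fusion of exactly two images; no registration,
  resampling or bias correction (inputs must be pre-registered — the
  package only verifies equal shapes).
- The VIFF metric is not implemented (the source method defines it only
  by citation); `evaluate()` reports the slot as `None`.
- The literal weight mode reproduces a published table that is not a
  partition of unity; it exists for auditability, not for use.
- Metric values are implementation-parameterized where the literature
  varies (Sobel scaling, window sizes); cross-paper comparisons should
  recompute metrics with one implementation throughout.
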