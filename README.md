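# medfuse

Two-stage fusion of co-registered CT and MR brain images, with the
standard objective fusion-quality metrics.

CT and MR are complementary: CT renders high-density structure (skull,
calcifications) at high intensity but shows little soft-tissue contrast;
MR renders soft tissue — and, on T2, lesions — with rich texture. Image
fusion combines one slice of each modality into a single image that keeps
the diagnostically salient content of both. `medfuse` implements a
two-stage method:

**Stage 1 — feature-weighted fusion.** Each image gets a global-contrast
saliency map, S(c_l) = Σ_j f_j |c_l − c_j| over its intensity histogram
(pixels of a rare, bright intensity score highest), thresholded (Otsu by
default) into a binary mask of high-intensity structures. In parallel,
the per-pixel structure tensor G = K_ρ ∗ (∇I ∇Iᵀ) yields eigenvalues
λ1 ≥ λ2 ≥ 0 and the scalar structure feature
m = (λ1+λ2)/2 + α_st (λ1−λ2)/2. Where exactly one modality is salient it
wins outright (weight 1); elsewhere the normalized structure features
m_A/(m_A+m_B) decide. The weights form a partition of unity and give the
initial fusion F0 = w1·I_ct + w2·I_mr.

**Stage 2 — variational refinement.** F0 is refined by minimizing the
convex energy

    E(u) = (α/2) Σ (u − F0)²  +  Σ |∇u − ∇I_mr|

whose fidelity term anchors the stage-1 intensities while the
total-variation-type term pulls the gradient field of u toward the MR
image, transferring soft-tissue texture. The saddle-point form
min_u max_{|p|≤1} is solved by an extrapolated primal–dual
(Chambolle–Pock) iteration, stable for στ‖∇‖² ≤ 1 with ‖∇‖² ≤ 8.

**Metrics.** `medfuse.metrics` provides spatial frequency (SF),
normalized fusion mutual information (MI), the Xydeas–Petrović
edge-transfer measure Q^AB/F, and Piella's weighted quality index Q_W,
all on the conventional 0–255 intensity scale.

## Worked example

No patient data ships with the package; deterministic CT/MR-like phantom
pairs (bright skull ring on CT, textured tissue plus a bright lesion on
MR) make every stage runnable out of the box:

```python
from medfuse import VariationalFusion, make_pair

ct, mr, truth = make_pair()          # 128x128 co-registered pair + masks
res = VariationalFusion(ct, mr).fit()
print(res.summary())
```

```
Two-stage CT/MR variational fusion
==================================================
image size:            128 x 128
weight mode:           symmetric
saliency threshold:    otsu
alpha_st / rho:        0.5 / 1.0
alpha_fid:             8.0
sigma / tau:           0.35 / 0.35
iterations run:        300 (cap 300)
energy of F0:          597.033131
final energy:          574.754232
last relative change:  2.316e-05
--------------------------------------------------
SF:                    35.2486
MI:                    1.1433
Q_abf:                 0.6228
Q_w:                   0.6982
```

The solve lowers the energy of the stage-1 image (597.03 → 574.75) by
transferring MR gradients; MI = 1.14 (of a maximum 2) says the fused
image shares substantial intensity information with both sources, and
Q_abf = 0.62 / Q_w = 0.70 quantify edge and structural transfer. On the
phantom ground truth the fused skull ring stays brighter than the
interior and the lesion keeps ≥ 100% of its MR intensity
(`res.fused[truth.lesion].mean()`).

The same pipeline from the shell:

```bash
medfuse phantom --out-dir demo --size 128
medfuse fuse demo/ct.png demo/mr.png -o demo/fused.png --report demo/run.json
medfuse evaluate demo/ct.png demo/mr.png demo/fused.png --json demo/metrics.json
```

`fuse` accepts `--alpha-fid --sigma --tau --max-iter --tol --alpha-st
--rho --mode symmetric|literal --debug-dir` and a `--config` file of flat
`key = value` lines (flags win); `--debug-dir` dumps every intermediate
map (saliency, masks, structure features, weights, F0) as PNGs. Runs are
bit-reproducible and the JSON report records input hashes, the full
effective configuration, iteration count and energies.

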