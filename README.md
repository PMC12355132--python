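# histo25d

**Morphology-preserving co-alignment of serial histology sections into
2.5D cores, with a divided depth/space attention encoder and
attention-based multiple-instance grading.**

Routine pathology cuts a needle-core biopsy into 6–16 serial ribbons,
each scanned as an independent 2-D whole-slide image. The tissue is one
volume, but the volumetric context is lost: each ribbon lands on the
glass with its own rotation, translation, slight scale and smooth
sectioning distortion. `histo25d` reconstructs the stack — a *2.5D
core* — so consecutive sections can be scrolled through in register and
fed as 256×256×Z patches to depth-aware models, while guaranteeing that
registration itself cannot deform the diagnostic morphology:

1. **Tissue/ribbon extraction** — HSV hue thresholding with
   morphological cleanup; connected-component ribbon labeling.
2. **Serial rigid registration** — SIFT keypoints, mutual-nearest /
   Lowe-ratio matching, RANSAC similarity fits
   (`p' = s·R(θ)·p + t`; no shear, no reflection), each section chained
   against the rendered previous section.
3. **Boundary-driven non-rigid registration** — a cubic B-spline
   free-form displacement field minimizing the mean squared difference
   of the *signed distance transforms of the ribbon boundaries* (outer
   contour plus gland-lumen rims) with bending-energy and displacement
   priors. Interior texture never enters the objective.

Alignment quality is scored as a registration error in physical units:
per adjacent pair, the median keypoint distance in microns; per core,
the match-count-weighted mean of pair medians.

On top of the cores, the package ships desk-scale reference
implementations of the model components: a divided depth/space
attention ("TimeSformer-style") patch encoder with recorded attention
maps, DINO-style momentum self-distillation with hand-written backprop,
combined space–time attention rollout
(`W[(i,j),(p,q)] = S[i,j,p]·T[p,j,q]`), and gated attention-based
multiple-instance (ABMIL) grading with CS (grade group ≥ 2)
binarization, McNemar model comparison and quadratic-weighted kappa.

A seeded phantom generator produces synthetic serial-section stacks —
H&E-like elliptical ribbons with known similarity corruptions, smooth
warps, landmarks and masks — so the whole pipeline is testable without
any data download.

## Worked example

```python
import numpy as np
from histo25d import PhantomSpec, generate_phantom_core, align_stack, extract_patches

# an 8-section synthetic core: ±10° rotation, 3% scale, ±20 px shift,
# 6 px smooth warps, known ground truth
stack = generate_phantom_core(PhantomSpec(seed=7))

result = align_stack(stack.sections, seed=0)
for name, rep in result.reports.items():
    print(f"{name:>12}: {rep.core_error_um:.2f} um")

true = stack.true_transforms[3]
est = result.transforms[3]
print(f"section 3: dtheta={abs(np.degrees(est.theta-true.theta)):.3f} deg, "
      f"dscale={abs(est.scale-true.scale):.4f}, "
      f"dt=({abs(est.tx-true.tx):.2f}, {abs(est.ty-true.ty):.2f}) px")

patches = extract_patches(result.core, patch_px=64)
print(f"{len(patches)} patches with >60% tissue, Z={result.core.n_sections}")
```

prints

```
unregistered: 10.38 um
       rigid: 0.95 um
    nonrigid: 0.56 um
section 3: dtheta=0.627 deg, dscale=0.0057, dt=(1.63, 0.63) px
7 patches with >60% tissue, Z=8
```

— the raw stack is misaligned by ~10 µm median keypoint distance
(~21 px at 0.5 µm/px); the rigid stage recovers the planted similarity
transforms to sub-degree/pixel-scale accuracy even though the 6 px
warps bias the fit (on warp-free phantoms recovery is several times
tighter), and the boundary-driven non-rigid stage roughly halves the
remaining error without touching interior texture.

The CLI mirrors the library:

```bash
histo25d phantom -o out/phantom --sections 8 --seed 7
histo25d align out/phantom -o out/aligned --mpp 0.5
histo25d patch out/aligned/core.zarr -o out/patches
histo25d eval-reg out/aligned
histo25d encode-demo -o out/encoder      # distillation smoke run + rollout heat maps
histo25d grade-demo -o out/mil           # ABMIL on the synthetic signal-bag task
```

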