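# sparsect

Sparse-view micro-CT reconstruction and vascular analysis.

Preclinical contrast-enhanced micro-CT can build 3D geometric models of
small vessels (e.g. the murine aortic arch) in vivo, but longitudinal
studies pay for it in X-ray dose and scan time. Acquiring fewer projection
views cuts both proportionally — at the price of streak artefacts and
noise that conventional filtered back projection (FBP/FDK) cannot
suppress. `sparsect` implements the full chain needed to quantify that
trade-off:

- **Simulation** — an aortic-arch-like vessel phantom (1.2 mm tube on a
  0.1 mm voxel grid, soft-tissue body, bone insert) with exact analytic
  ground truth, projected with Beer–Lambert physics and Poisson photon
  noise over a circular fan- or cone-beam trajectory, and retrospective
  view subsampling (keep every *n*-th of the full view set).
- **Reconstruction** — the image space reconstruction algorithm (ISRA), a
  multiplicative nonnegative iteration
  `x_j ← x_j · [Bm]_j / [BAx]_j`
  that back-projects the measured sinogram `m` once and then works purely
  in image space; its one-step-late total-variation variant (ISRA-TV)
  `x_j ← x_j · [Bm]_j / ([BAx]_j + λ ∂U/∂x_j)`
  with the smoothed isotropic TV energy
  `U(x) = Σ_j √(Σ_axes (∇x)_j² + δ²)` evaluated at the previous iterate
  (λ = 0.001 by default); and an FBP/FDK baseline. Iterations stop when
  the percent relative image change falls below 0.14.
- **Segmentation** — the semi-automatic protocol: seed-VOI statistics,
  thresholding to `[max(v_min, v̄−3σ), min(v_max, v̄+3σ)]`, one-voxel
  erosion, region growing from the VOI, one-voxel dilation, hole filling
  (all with the 26-neighbourhood in 3D, 8 in 2D).
- **Evaluation** — TP/FP/FN voxel classification against a full-view
  reference, skeleton-based centerlines with per-point best-fit diameters
  measured on planes orthogonal to the local tangent, mean relative
  diameter error and mean 3D centerline distance over closest-point
  matched control pairs, and paired Student's t-tests between conditions.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import numpy as np
from sparsect import (make_geometry, make_vessel_phantom, simulate_projections,
                      isra, isra_tv, ReconConfig, tv_energy, segment_vessels,
                      classify_voxels, extract_centerline, Centerline,
                      centerline_distance, VolumeImage)
from sparsect.phantom import PhantomConfig
from sparsect.pipeline import seed_voi_from_truth

# 1. phantom with analytic truth: 1.2 mm vessel at 0.1 mm voxels
truth = make_vessel_phantom(PhantomConfig(), seed=7)
voi = seed_voi_from_truth(truth)
mask = segment_vessels(truth.attenuation, voi)
counts = classify_voxels(mask, truth.vessel_mask)
line = extract_centerline(mask)
ref = Centerline(truth.centerline_points, truth.centerline_tangents,
                 truth.diameter_profile)
print(f"noise-free segmentation: TP {counts.tp_fraction:.3f} "
      f"FP {counts.fp_fraction:.3f}")
print(f"recovered diameter      {np.mean(line.diameters):.3f} mm "
      f"(truth {truth.mean_diameter:.1f} mm)")
print(f"centerline offset       {centerline_distance(line, ref):.3f} mm")

# 2. sparse-view reconstruction: 32 of 512 views, Poisson noise
geom = make_geometry(n_views=32, detector_count=288)
proj = simulate_projections(truth, geom, photons_per_pixel=1e4, seed=7)
x0 = VolumeImage(np.full(truth.attenuation.values.shape, 0.02), 0.1)
rc = ReconConfig(max_iterations=150, stop_threshold=1e-9)
plain, _ = isra(proj, x0=x0, cfg=rc)
reg, _ = isra_tv(proj, x0=x0, cfg=rc)   # lam = 0.001
print(f"32-view TV energy: ISRA {tv_energy(plain, 1e-6):.1f}  "
      f"ISRA-TV {tv_energy(reg, 1e-6):.1f}")
```

prints

```
noise-free segmentation: TP 1.000 FP 0.000
recovered diameter      1.215 mm (truth 1.2 mm)
centerline offset       0.043 mm
32-view TV energy: ISRA 199.3  ISRA-TV 55.8
```

The segmentation chain recovers the analytic vessel exactly on noise-free
data; the extracted centerline sits within half a voxel of the analytic
one and the measured diameter within 0.015 mm of the 1.2 mm truth. At a
16-fold view reduction, TV regularization cuts the total variation of the
reconstruction — a direct proxy for streak/noise content — by ~3.6×.

The full experiment matrix (algorithms × view levels, each condition
reconstructed, segmented and scored against the full-view reference of its
algorithm family) is driven by `sparsect.pipeline.run_experiment`, or from
the shell:

```
sparsect phantom --seed 7 --out truth/
sparsect recon --algo isra-tv --sinogram sino --views 256 --out vol.mhd
sparsect segment --in vol.mhd --voi voi.mhd --out mask.mhd
sparsect evaluate --test mask.mhd --ref refmask.mhd --report report.json
sparsect run-all --seed 7 --out results/
```

Volumes and masks are read/written as MetaImage (.mhd/.raw) or NIfTI,
sinograms as flat binary with a JSON sidecar; every pipeline run writes an
aggregate CSV plus a provenance record (config hash, seeds, versions).

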