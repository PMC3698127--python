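# Methods

`sparsect` studies how far the number of projection views in a micro-CT
acquisition of a contrast-enhanced vessel can be reduced — cutting X-ray
dose and scan time proportionally — before the vascular geometry extracted
from the images (segmentation overlap, centerline position, vessel
diameters) degrades. Because retrospectively subsampled in vivo data are
rarely shareable, the toolkit is built around a synthetic vascular phantom
with exact analytic ground truth; every algorithm also works on imported
sinograms and volumes.

## Acquisition model

A point X-ray source and a flat detector rotate on a circle around the
isocenter (fan-beam in 2D, circular cone-beam in 3D). Defaults follow a
small-animal protocol: magnification 3.5 (SAD 50 mm, SDD 175 mm — absolute
distances are an assumption; only their ratio enters any reported metric),
0.35 mm detector pixels (0.1 mm at the isocenter), 0.1 mm reconstruction
voxels, uniformly spaced view angles over 360°. Detector pixel count
defaults to 1.5× the grid size so the field of view covers the phantom.

Projection simulation follows Beer–Lambert: line integrals `L` of the
attenuation map (mm⁻¹), expected counts `I₀·exp(−L)` per detector pixel,
Poisson noise, and log transformation `m = −ln(max(c,1)/I₀)`. The clamp at
one count keeps `m` finite at starved budgets. Dose can be emulated two
ways: retrospective view subsampling at fixed `I₀` (keep every n-th view;
the default, matching how sparse-view protocols are studied) or reducing
`I₀` at a fixed view count (tube-current reduction). Nominal dose is
reported as `full_dose · views/full_views` (120 mGy at 2048 views gives
60/30/15/7.5/3.75/1.875 mGy down to 32 views).

The forward projector is pixel-driven: samples along each source→pixel ray
at half-voxel steps with (bi/tri)linear interpolation. The back projector
is voxel-driven: each voxel is projected onto the detector and the detector
row interpolated linearly. The pair is deliberately unmatched, mirroring
GPU texture-based implementations; a dense system-matrix oracle built with
the exact same sampling rule provides a matched pair (`A`, `Aᵀ`) for
convergence studies and verifies the ray-driven projector to ~1e-14
relative. Focal-spot size, scatter, beam hardening and detector tilt are
not modelled. Rotation invariance of projections holds to machine precision
only at grid-symmetric (90°) angles; at arbitrary angles voxelization
limits agreement to ~2%.

## Reconstruction

**FBP/FDK.** Cosine weighting, ramp filtering (spatial-domain
Ramachandran–Lakshminarayanan kernel, optionally apodized with Hann,
Shepp–Logan or cosine windows) on the virtual detector at the isocenter,
and `1/U²` distance-weighted back projection; in 3D the Feldkamp scheme
(row-wise filtering with the full cone-beam cosine weight). On a noiseless
full-view disc the unapodized reconstruction is exact in scale with RMSE
≈ 3% of contrast; the pipeline default is the Hann window, which trades
edge sharpness for noise suppression.

**ISRA.** The image space reconstruction algorithm iterates
`x ← x · Bm / B(Ax)` with forward projector `A` and back projector `B`:
multiplicative, nonnegativity-preserving, and touching the measured
sinogram exactly once (`Bm` is computed at the start and cached — the
design that makes the method attractive for very large sinograms). With a
matched pair the data-fit objective `‖Ax−m‖²` is non-increasing and the
limit is a nonnegative least-squares solution (verified against
`scipy.optimize.nnls` to <1e-3 relative objective gap); the default
unmatched pair carries no such guarantee, which is the standard trade-off.
Negative log-sinogram values (noise) are clipped to zero before `Bm`, with
the count recorded. The start image is uniform positive at the mean
back-projection scale (multiplicative updates need strict positivity).
The recorded objective uses `‖Ax‖² − 2⟨x, Bm⟩ + ‖m‖²`, exact for matched
pairs and a surrogate otherwise, so the sinogram is still read only once.

**ISRA-TV.** One-step-late regularization inserts the gradient of a
smoothed isotropic total-variation energy
`U(x) = Σⱼ √(Σ_axes (forward difference)² + δ²)` into the denominator,
evaluated at the previous iterate:
`x ← x · Bm / (B(Ax) + λ·∂U/∂x)`. Discretization: forward differences,
replicate (zero-gradient) boundary, δ inside the square root (default
1e-6); a constant N-voxel image has `U = N·δ` and `U` is shift-invariant.
The analytic gradient is validated against numeric differentiation to
1e-5.

The penalty weight follows the view-summed convention: `λ` multiplies
`∂U` against back projections summed over views, so the absolute penalty
strength is independent of subsampling and its strength *relative to the
data term* grows as views are removed — full-view reconstructions are
barely smoothed while sparse-view reconstructions are strongly
regularized, which is the behaviour the method exists for. (Numerically
both back projections are divided by the view count for conditioning and
`λ` is rescaled by `256/n_views`; 256 views is the calibration point, at
which a λ-scan on the 64² phantom showed λ = 0.001 minimizes
reconstruction RMSE — strong regularization without over-smoothing.)
`λ = 0` reproduces plain ISRA bit for bit.

OSL gives no positivity guarantee for the denominator: non-positive
denominators are clamped to `1e-12 × max(denominator)` and counted in the
convergence trace. Within the stable window (λ ≲ 2–3× the default at 32
views) TV energy decreases monotonically with λ; far beyond it the clamped
iteration destabilizes rather than approaching the flat-image limit, so no
such limit is claimed. No ordered subsets are used anywhere.

**Stopping.** Iterations stop when the percent relative L2 change between
successive iterates, `100·‖xₖ−xₖ₋₁‖/‖xₖ‖`, drops to 0.14 (an empirical
percent-scale threshold; configurable) or at the iteration cap.

## Phantom

An aortic-arch-like tube: a circular arc (semi-torus in 3D) of radius
2.5 mm and tube radius 0.6 mm (1.2 mm diameter) in a circular soft-tissue
body with a bone-like insert and air outside. Attenuation levels
(background 0.02, vessel 0.06, bone 0.10 mm⁻¹) are plausible contrast
ratios for iodine-enhanced blood, not measured values. A voxel belongs to
the truth mask iff its centre lies inside the analytic tube; the analytic
centerline is sampled at ≤1 voxel spacing with per-point diameters. An
optional straight branch (carotid-like) extends from the arch apex;
default off. Everything is deterministic given the configuration; the seed
feeds only the Poisson noise.

What the phantom does *not* emulate: real murine anatomy, cardiac and
respiratory motion, contrast washout, polychromatic spectra, detector
non-idealities. Passing tests therefore demonstrate the algorithmic chain
(reconstruction → segmentation → quantification) under controlled noise
and sampling, not in vivo performance.

## Segmentation

The semi-automatic chain: intensity statistics (mean, *sample* SD, min,
max) inside a user-provided seed VOI; thresholding to
`[max(v_min, v̄−3σ), min(v_max, v̄+3σ)]` (bounds inclusive); erosion by one
voxel (26-neighbourhood in 3D, 8 in 2D; outside the grid counts as
background) to detach noise speckle; region growing from the VOI
(26-connected components of the thresholded-and-eroded mask); dilation by
one voxel to regain the eroded shell; hole filling.

Two hole-filling modes ship. The literal rule — voxel OR its 26
neighbours — equals one dilation pass: it closes one-voxel holes but also
adds a one-voxel shell around every boundary (for a thin vessel that alone
is a false-positive fraction of roughly perimeter/area, ~0.24 on the
default phantom) and cannot reach the centre of cavities 3 voxels wide.
The pipeline default is therefore topological flood-fill hole filling;
literal mode remains selectable for fidelity to the one-pass description.

The pipeline derives its seed VOI from the true centerline: a tube of half
the vessel radius along the middle third of the arch. The min/max clamps
of the threshold interval make the VOI's *observed* range the binding
bound, so a tiny spherical VOI collapses the segmentation; an elongated
intra-vessel VOI samples the along-vessel intensity variation the way a
user-drawn vessel VOI does.

## Evaluation

Voxel classification against a reference mask: TP, FP, FN with fractions
normalized by the reference size (TP+FN = |reference| exactly). Following
the study design, sparse-view conditions are referenced against the
full-view reconstruction of the same algorithm family — ISRA and ISRA-TV
against full-view ISRA, FBP against full-view FBP — not against phantom
truth.

Centerlines are extracted by skeletonization (`skimage`), tracing the
longest geodesic path through the 26-connected skeleton graph (two
Dijkstra passes; exact on trees, best effort with a warning if cycles
remain), moving-average smoothing (window 5), resampling at 2-voxel
spacing, central-difference tangents, and one trimmed control point per
end (tube end caps bias tangents and cross-sections). Replacing a
proprietary centerline tool, the full-view reference condition is scored
by re-extracting its own centerline with a different smoothing window
(7 vs 5), mirroring the error floor of segmenting a reference dataset
twice.

Per control point, the diameter is measured on the plane orthogonal to the
local tangent: the mask is resampled at half-voxel steps, the connected
cross-section containing the point isolated, and the equivalent-area
circle diameter `2√(area/π)` reported (in 2D, the chord length); a
least-squares circle fit to the section boundary is an alternative mode.
Both are approximations to an unknowable "best-fit" definition. Control
points are matched to the *nearest reference control point* (point-to-
point, ties to the lower index); reported metrics are the mean relative
diameter error `⟨|d−d_ref|/d_ref⟩·100%` and the mean Euclidean distance
over matched pairs. Conditions are compared with a two-tailed Student's
t-test, paired across subjects by default, raw p against 0.05 (no
multiple-testing correction). Identical paired samples report p = 1 with a
warning instead of NaN. No rigid pre-alignment is applied before
centerline comparison (available but off, matching the reference
protocol).

## Scaled-down study

The canonical desk-scale experiment (`sparsect.pipeline.trend_study`) uses
a fan-beam 192² grid at 0.1 mm pitch, 512 full views subsampled to 256 and
128, I₀ = 10⁴ photons/pixel, ISRA and ISRA-TV (λ = 0.001, stop 0.14,
250-iteration cap), seed 7. These sizes keep the full matrix to a few
minutes on one CPU while preserving the noise-vs-sampling regime of
interest. Measured behaviour: ISRA false-positive fraction grows strictly
as views drop (0 → 0.07 → 0.12) and its diameter error roughly triples
(4.3% → 12.3%), while ISRA-TV holds FP near its full-view level
(0.038–0.056), keeps diameter errors at 6.9–8.4%, and keeps every
centerline offset below the voxel pitch. Individual condition values move
by a few hundredths (FP fractions) or a few percentage points (diameter
errors) across noise seeds; the qualitative ordering is stable, and the
fixed-seed protocol makes the study reproducible.

## Known limitations

- The unmatched default projector pair voids ISRA's monotonicity theory;
  use `matched_pair` (small instances) when convergence guarantees matter.
- OSL-TV has no convergence or positivity theory; diverges for large λ.
- The stopping threshold 0.14 is empirical and interacts with the
  iteration cap; ISRA-TV typically hits the cap at desk scale.
- Skeleton-based centerlines degrade on masks with holes, branches or
  cycles (warned, best effort).
- 3D (cone-beam) paths share all code and contracts but default to small
  grids; the full 2048-view 3D protocol is configuration-reachable, not a
  test default.
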