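"""Synthetic vascular phantom and projection simulation.

The phantom emulates a contrast-enhanced curved vessel — an aortic-arch-like
tube of ~1.2 mm diameter bent into a circular arc (a semi-torus in 3D) —
embedded in a circular soft-tissue body with an optional bone-like insert
and air outside the body.  An analytic centerline with per-point diameters
is carried along as ground truth, so reconstruction/segmentation error can
be measured against exact geometry.

Projections follow the Beer-Lambert law: expected counts
``I0 * exp(-L)`` for line integrals ``L``, Poisson noise on the counts, and
log transformation back to noisy line integrals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from sparsect.geometry import ProjectionData, ScanGeometry, VolumeImage, forward_project
from sparsect.segment import BinaryMask


class ResolutionError(ValueError):
    """Tube too thin for the voxel grid."""


@dataclass
class PhantomConfig:
    """Geometry and attenuation of the vessel phantom.

    Lengths in mm, attenuation in mm^-1.  The arc spans ``arc_span`` radians
    around ``arch_center`` (in the rotation plane; 3D arcs lie in the plane
    of the middle slice).  ``branch_length > 0`` adds a straight tube from
    the arch apex pointing radially outward (a carotid-like branch).
    Attenuation levels are plausible soft-tissue / contrast-enhanced blood /
    bone contrast, not measured values.
    """

    shape: tuple = (192, 192)
    voxel_pitch: float = 0.1
    arch_center: tuple = (0.0, -1.0)
    arch_radius: float = 2.5
    tube_radius: float = 0.6
    arc_span: tuple = (0.0, math.pi)
    branch_length: float = 0.0
    branch_radius: float | None = None
    body_radius: float | None = None
    mu_background: float = 0.02
    mu_vessel: float = 0.06
    mu_bone: float = 0.10
    bone_center: tuple = (0.0, -4.5)
    bone_radius: float = 0.8
    include_bone: bool = True


@dataclass
class PhantomTruth:
    """Ground truth bundle: attenuation map, vessel mask, analytic
    centerline (points, tangents) and per-point diameters."""

    attenuation: VolumeImage
    vessel_mask: BinaryMask
    centerline_points: np.ndarray
    centerline_tangents: np.ndarray
    diameter_profile: np.ndarray
    config: PhantomConfig
    seed: int

    @property
    def mean_diameter(self) -> float:
        return float(self.diameter_profile.mean())


def _voxel_center_grid(shape, pitch, origin):
    axes = [origin[ax] + (np.arange(n) + 0.5) * pitch
            for ax, n in enumerate(shape)]
    return np.meshgrid(*axes, indexing="ij")


def _distance_to_arc(p0, p1, center, radius, span):
    """In-plane distance from points to a circular arc."""
    d0 = p0 - center[0]
    d1 = p1 - center[1]
    r = np.hypot(d0, d1)
    phi = np.mod(np.arctan2(d1, d0), 2 * np.pi)
    lo, hi = span
    on_arc = (phi >= lo) & (phi <= hi)
    dist = np.where(on_arc, np.abs(r - radius), np.inf)
    for ang in (lo, hi):
        e0 = center[0] + radius * math.cos(ang)
        e1 = center[1] + radius * math.sin(ang)
        dist = np.minimum(dist, np.hypot(p0 - e0, p1 - e1))
    return dist


def _distance_to_segment(p0, p1, a, b):
    ab0, ab1 = b[0] - a[0], b[1] - a[1]
    denom = ab0 * ab0 + ab1 * ab1
    t = np.clip(((p0 - a[0]) * ab0 + (p1 - a[1]) * ab1) / denom, 0.0, 1.0)
    return np.hypot(p0 - (a[0] + t * ab0), p1 - (a[1] + t * ab1))


def make_vessel_phantom(cfg: PhantomConfig | None = None,
                        seed: int = 0) -> PhantomTruth:
    """Rasterise the analytic phantom onto the voxel grid.

    A voxel belongs to the vessel mask iff its centre lies within
    ``tube_radius`` of the analytic centerline curve.  Fully deterministic
    given the configuration; ``seed`` is recorded for provenance and used
    by downstream noise simulation.
    """
    cfg = cfg if cfg is not None else PhantomConfig()
    ndim = len(cfg.shape)
    if ndim not in (2, 3):
        raise ValueError("phantom must be 2D or 3D")
    pitch = cfg.voxel_pitch
    if cfg.tube_radius < 2 * pitch:
        raise ResolutionError(
            f"tube radius {cfg.tube_radius} mm is below 2 voxels at "
            f"{pitch} mm pitch; the diameter would not be resolvable")
    origin = tuple(-n * pitch / 2 for n in cfg.shape)
    grids = _voxel_center_grid(cfg.shape, pitch, origin)
    p0, p1 = grids[0], grids[1]

    # in-plane distance to the centerline (arc + optional branch)
    dist2d = _distance_to_arc(p0, p1, cfg.arch_center, cfg.arch_radius,
                              cfg.arc_span)
    apex_angle = 0.5 * (cfg.arc_span[0] + cfg.arc_span[1])
    apex_dir = np.array([math.cos(apex_angle), math.sin(apex_angle)])
    apex = np.asarray(cfg.arch_center) + cfg.arch_radius * apex_dir
    if cfg.branch_length > 0:
        tip = apex + cfg.branch_length * apex_dir
        branch_d = _distance_to_segment(p0, p1, apex, tip)
        r_branch = cfg.branch_radius or cfg.tube_radius
        # separate tube radius for the branch: normalise distances
        dist2d = np.minimum(dist2d,
                            branch_d * (cfg.tube_radius / r_branch))
    if ndim == 3:
        z = grids[2] - 0.0  # arc lies in the central plane z = 0
        dist = np.sqrt(dist2d ** 2 + z ** 2)
    else:
        dist = dist2d
    vessel = dist <= cfg.tube_radius

    # soft-tissue body disc (air outside), optional bone insert
    extent = min(n * pitch for n in cfg.shape[:2])
    body_r = cfg.body_radius if cfg.body_radius is not None else 0.45 * extent
    body = np.hypot(p0, p1) <= body_r
    mu = np.zeros(cfg.shape)
    mu[body] = cfg.mu_background
    if cfg.include_bone:
        bone2d = np.hypot(p0 - cfg.bone_center[0], p1 - cfg.bone_center[1])
        mu[(bone2d <= cfg.bone_radius) & body] = cfg.mu_bone
    mu[vessel] = cfg.mu_vessel

    # analytic centerline sampled at <= 1 voxel spacing
    arc_len = cfg.arch_radius * (cfg.arc_span[1] - cfg.arc_span[0])
    n_pts = max(int(math.ceil(arc_len / pitch)) + 1, 2)
    phis = np.linspace(cfg.arc_span[0], cfg.arc_span[1], n_pts)
    pts = np.stack([cfg.arch_center[0] + cfg.arch_radius * np.cos(phis),
                    cfg.arch_center[1] + cfg.arch_radius * np.sin(phis)], axis=1)
    tans = np.stack([-np.sin(phis), np.cos(phis)], axis=1)
    diams = np.full(n_pts, 2 * cfg.tube_radius)
    if cfg.branch_length > 0:
        nb = max(int(math.ceil(cfg.branch_length / pitch)) + 1, 2)
        ts = np.linspace(0.0, cfg.branch_length, nb)[1:]
        bpts = apex[None, :] + ts[:, None] * apex_dir[None, :]
        pts = np.vstack([pts, bpts])
        tans = np.vstack([tans, np.tile(apex_dir, (len(ts), 1))])
        r_branch = cfg.branch_radius or cfg.tube_radius
        diams = np.concatenate([diams, np.full(len(ts), 2 * r_branch)])
    if ndim == 3:
        pts = np.hstack([pts, np.zeros((len(pts), 1))])
        tans = np.hstack([tans, np.zeros((len(tans), 1))])

    attenuation = VolumeImage(mu, pitch, origin)
    mask = BinaryMask(vessel, pitch, origin)
    return PhantomTruth(attenuation, mask, pts, tans, diams, cfg, seed)


def simulate_projections(truth: PhantomTruth, geom: ScanGeometry,
                         photons_per_pixel: float | None = 1e4,
                         seed: int = 0) -> ProjectionData:
    """Beer-Lambert projection simulation with Poisson photon noise.

    ``photons_per_pixel`` is the unattenuated photon budget I0 per detector
    pixel per view; ``None`` or ``inf`` returns the noise-free line
    integrals exactly.  Detected counts are clamped at 1 so the log
    transform stays finite.  Deterministic given ``seed``.
    """
    line_integrals = forward_project(truth.attenuation, geom)
    if photons_per_pixel is None or math.isinf(photons_per_pixel):
        return line_integrals
    if photons_per_pixel <= 0:
        raise ValueError("photon budget must be positive")
    rng = np.random.default_rng(seed)
    expected = photons_per_pixel * np.exp(-line_integrals.values)
    counts = rng.poisson(expected).astype(float)
    m = -np.log(np.maximum(counts, 1.0) / photons_per_pixel)
    # ~10 sigma allowance for negative log values where the path is empty
    tol = 10.0 / math.sqrt(photons_per_pixel)
    return ProjectionData(m, geom, photon_budget=photons_per_pixel,
                          negative_tolerance=tol)
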