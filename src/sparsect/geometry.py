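"""Scan geometry, projection containers and ray-driven projectors.

The acquisition model is a circular trajectory around the isocenter with a
flat detector: fan-beam in 2D (``fan2d``) and circular cone-beam in 3D
(``cone3d``).  The forward projector is pixel-driven (samples along each
source->detector-pixel ray), the back projector is voxel-driven (each voxel
is mapped onto the detector); the pair is deliberately *unmatched*, as is
common in GPU-style implementations.  A dense system-matrix oracle built
with the exact same sampling rule is provided for small instances, both as
a verification tool and as a matched projector pair for convergence
studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from sparsect import _kernels

#: forward-projection sampling step, as a fraction of the voxel pitch
SAMPLE_STEP_FRACTION = 0.5

#: largest number of matrix elements the dense oracle will materialise
ORACLE_ELEMENT_CAP = 50_000_000


class GeometryConfigError(ValueError):
    """Raised for non-physical geometry parameters."""


@dataclass(frozen=True)
class ScanGeometry:
    """Circular-trajectory acquisition geometry.

    Parameters are in mm.  ``angles`` are the view angles in radians in
    ``[0, 2*pi)``; the default constructor :func:`make_geometry` spaces them
    uniformly over the full circle.  ``detector_rows`` is only meaningful in
    ``cone3d`` mode.
    """

    mode: str
    source_axis_distance: float
    source_detector_distance: float
    detector_pixel_pitch: float
    detector_count: int
    angles: np.ndarray
    detector_rows: int = 1

    def __post_init__(self):
        if self.mode not in ("fan2d", "cone3d"):
            raise GeometryConfigError(f"unknown mode {self.mode!r}")
        if self.source_axis_distance <= 0 or self.source_detector_distance <= 0:
            raise GeometryConfigError("source/detector distances must be positive")
        if self.magnification <= 1:
            raise GeometryConfigError("magnification must exceed 1")
        if self.detector_pixel_pitch <= 0:
            raise GeometryConfigError("detector pixel pitch must be positive")
        if self.detector_count < 1 or self.detector_rows < 1:
            raise GeometryConfigError("detector must have at least one pixel")
        angles = np.atleast_1d(np.asarray(self.angles, dtype=float))
        if angles.size < 1:
            raise GeometryConfigError("at least one view angle required")
        if np.any(angles < 0) or np.any(angles >= 2 * np.pi):
            raise GeometryConfigError("angles must lie in [0, 2*pi)")
        if angles.size > 1 and np.any(np.diff(angles) <= 0):
            raise GeometryConfigError("angles must be strictly increasing")
        object.__setattr__(self, "angles", angles)

    @property
    def n_views(self) -> int:
        return int(self.angles.size)

    @property
    def magnification(self) -> float:
        return self.source_detector_distance / self.source_axis_distance

    @property
    def fov(self) -> float:
        """Reconstructable field of view: detector width back-projected to
        the isocenter."""
        return self.detector_count * self.detector_pixel_pitch / self.magnification


@dataclass
class VolumeImage:
    """Scalar attenuation image (mm^-1) on a regular grid.

    ``voxel_pitch`` may be a scalar (isotropic, required by the projectors)
    or a per-axis sequence; ``origin`` holds the mm coordinates of the grid
    corner, so voxel centres sit at ``origin + (index + 0.5) * pitch``.
    """

    values: np.ndarray
    voxel_pitch: float | tuple
    origin: tuple | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (2, 3):
            raise ValueError("volume must be 2D or 3D")
        pitch = np.atleast_1d(np.asarray(self.voxel_pitch, dtype=float))
        if pitch.size == 1:
            pitch = np.full(self.values.ndim, pitch[0])
        if pitch.size != self.values.ndim or np.any(pitch <= 0):
            raise ValueError("voxel pitch must be positive, one value per axis")
        self.voxel_pitch = tuple(pitch)
        if self.origin is None:
            # centre the grid on the isocenter
            self.origin = tuple(-n * p / 2 for n, p in zip(self.values.shape, pitch))
        else:
            self.origin = tuple(float(o) for o in self.origin)

    @property
    def pitch(self) -> float:
        """Isotropic pitch; raises if the grid is anisotropic."""
        if len(set(self.voxel_pitch)) != 1:
            raise ValueError("operation requires an isotropic voxel grid")
        return self.voxel_pitch[0]

    @property
    def ndim(self) -> int:
        return self.values.ndim

    def copy_with(self, values: np.ndarray) -> "VolumeImage":
        return VolumeImage(values, self.voxel_pitch, self.origin)


@dataclass
class ProjectionData:
    """Log-transformed line-integral sinogram bound to a :class:`ScanGeometry`.

    ``values`` has shape (views, detector) in fan2d mode and
    (views, rows, detector) in cone3d mode; entries are dimensionless
    ``-ln(I/I0)`` line integrals.  Small negative excursions from noise are
    tolerated up to ``negative_tolerance``.
    """

    values: np.ndarray
    geometry: ScanGeometry
    photon_budget: float | None = None
    negative_tolerance: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected_ndim = 2 if self.geometry.mode == "fan2d" else 3
        if self.values.ndim != expected_ndim:
            raise ValueError(
                f"{self.geometry.mode} projections must be {expected_ndim}D, "
                f"got {self.values.ndim}D")
        if self.values.shape[0] != self.geometry.n_views:
            raise ValueError("first axis must match the number of view angles")
        if self.values.shape[-1] != self.geometry.detector_count:
            raise ValueError("last axis must match the detector count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("projection values must be finite")
        if self.values.min() < -abs(self.negative_tolerance) - 1e-12:
            raise ValueError("negative line integrals beyond the configured "
                             "noise tolerance")

    @property
    def n_views(self) -> int:
        return int(self.values.shape[0])


@dataclass
class SystemMatrixOracle:
    """Dense system matrix A with a_ij = contribution of voxel j to ray i.

    Rows are ordered view-major (then detector row, then detector column);
    columns follow C-order flattening of the volume grid.  Intended for
    small instances: verification of the ray-driven projectors and matched
    forward/transpose projection in convergence tests.
    """

    matrix: np.ndarray
    geometry: ScanGeometry
    volume_shape: tuple

    def forward(self, vol_values: np.ndarray) -> np.ndarray:
        out = self.matrix @ np.asarray(vol_values, dtype=float).ravel()
        return out.reshape(self._sino_shape())

    def back(self, sino_values: np.ndarray) -> np.ndarray:
        out = self.matrix.T @ np.asarray(sino_values, dtype=float).ravel()
        return out.reshape(self.volume_shape)

    def _sino_shape(self) -> tuple:
        g = self.geometry
        if g.mode == "fan2d":
            return (g.n_views, g.detector_count)
        return (g.n_views, g.detector_rows, g.detector_count)


def make_geometry(n_views: int,
                  detector_count: int = 288,
                  detector_pixel_pitch: float = 0.35,
                  source_axis_distance: float = 50.0,
                  source_detector_distance: float = 175.0,
                  mode: str = "fan2d",
                  detector_rows: int = 1,
                  full_angle: float = 2 * np.pi) -> ScanGeometry:
    """Build a uniformly sampled circular-trajectory geometry.

    Defaults give 3.5x magnification (SAD 50 mm, SDD 175 mm) so a 0.35 mm
    detector pixel maps to 0.1 mm at the isocenter; absolute distances are
    an assumption, only their ratio enters the reported metrics.
    """
    if n_views < 1:
        raise GeometryConfigError("need at least one view")
    angles = np.arange(n_views) * (full_angle / n_views)
    return ScanGeometry(
        mode=mode,
        source_axis_distance=source_axis_distance,
        source_detector_distance=source_detector_distance,
        detector_pixel_pitch=detector_pixel_pitch,
        detector_count=detector_count,
        angles=angles,
        detector_rows=detector_rows if mode == "cone3d" else 1,
    )


def _check_dim(vol: VolumeImage, geom: ScanGeometry) -> None:
    expected = 2 if geom.mode == "fan2d" else 3
    if vol.ndim != expected:
        raise ValueError(f"{geom.mode} requires a {expected}D volume, "
                         f"got {vol.ndim}D")


def _sampling(vol: VolumeImage, geom: ScanGeometry):
    """Ray sampling interval shared by the kernel and the oracle.

    Samples cover a symmetric interval around the isocenter large enough to
    contain the whole grid, at step ``SAMPLE_STEP_FRACTION * pitch``.
    """
    pitch = vol.pitch
    corners = []
    for axis, (n, o) in enumerate(zip(vol.values.shape, vol.origin)):
        corners.append((o, o + n * pitch))
    radius = math.sqrt(sum(max(lo * lo, hi * hi) for lo, hi in corners)) + pitch
    h = SAMPLE_STEP_FRACTION * pitch
    t_start = geom.source_axis_distance - radius
    n_samples = int(math.ceil(2 * radius / h)) + 1
    return h, t_start, n_samples


def forward_project(vol: VolumeImage, geom: ScanGeometry) -> ProjectionData:
    """Pixel-driven forward projection: line integrals of ``vol`` (mm^-1)
    along every source->detector-pixel ray, in dimensionless units."""
    _check_dim(vol, geom)
    h, t_start, ns = _sampling(vol, geom)
    if geom.mode == "fan2d":
        sino = _kernels.fan_forward(
            vol.values, vol.origin[0], vol.origin[1], vol.pitch, geom.angles,
            geom.source_axis_distance, geom.source_detector_distance,
            geom.detector_pixel_pitch, geom.detector_count, h, t_start, ns)
    else:
        sino = _kernels.cone_forward(
            vol.values, vol.origin[0], vol.origin[1], vol.origin[2], vol.pitch,
            geom.angles, geom.source_axis_distance,
            geom.source_detector_distance, geom.detector_pixel_pitch,
            geom.detector_rows, geom.detector_count, h, t_start, ns)
    # the projector is linear, so synthetic volumes may produce negative
    # line integrals; the nonnegativity contract applies to measured data
    return ProjectionData(sino, geom, negative_tolerance=np.inf)


def back_project(proj: ProjectionData, geom: ScanGeometry | None = None,
                 vol_template: VolumeImage | None = None,
                 fbp_weight: bool = False) -> VolumeImage:
    """Voxel-driven back projection of a sinogram onto the template grid.

    Each voxel accumulates, over all views, the linearly interpolated
    detector value at its projected position (optionally with the fan/cone
    beam ``1/U^2`` distance weighting used by filtered back projection).
    """
    geom = geom if geom is not None else proj.geometry
    if vol_template is None:
        vol_template = default_volume(geom)
    _check_dim(vol_template, geom)
    if proj.values.shape[0] != geom.n_views:
        raise ValueError("projection data not bound to this geometry")
    shape = vol_template.values.shape
    if geom.mode == "fan2d":
        out = _kernels.fan_back(
            np.ascontiguousarray(proj.values), vol_template.origin[0],
            vol_template.origin[1], vol_template.pitch, shape[0], shape[1],
            geom.angles, geom.source_axis_distance,
            geom.source_detector_distance, geom.detector_pixel_pitch,
            fbp_weight)
    else:
        out = _kernels.cone_back(
            np.ascontiguousarray(proj.values), vol_template.origin[0],
            vol_template.origin[1], vol_template.origin[2],
            vol_template.pitch, shape[0], shape[1], shape[2], geom.angles,
            geom.source_axis_distance, geom.source_detector_distance,
            geom.detector_pixel_pitch, fbp_weight)
    return vol_template.copy_with(out)


def default_volume(geom: ScanGeometry, voxel_pitch: float = 0.1) -> VolumeImage:
    """Zero volume covering the geometry's field of view at the given pitch
    (default 0.1 mm), centred on the isocenter."""
    n = int(round(geom.fov / voxel_pitch))
    shape = (n, n) if geom.mode == "fan2d" else (n, n, geom.detector_rows)
    return VolumeImage(np.zeros(shape), voxel_pitch)


def build_system_matrix(geom: ScanGeometry, vol_template: VolumeImage,
                        model: str = "ray") -> SystemMatrixOracle:
    """Materialise the dense system matrix of :func:`forward_project`.

    ``model='ray'`` reproduces the pixel-driven sampling rule exactly, so
    ``A @ x.ravel()`` equals ``forward_project(x)`` up to floating-point
    summation order.  ``model='identity'`` is a test hook: one ray per
    voxel with unit weight.
    """
    _check_dim(vol_template, geom)
    shape = vol_template.values.shape
    n_vox = int(np.prod(shape))
    if model == "identity":
        return SystemMatrixOracle(np.eye(n_vox), geom, shape)
    if model != "ray":
        raise ValueError(f"unknown system model {model!r}")
    n_rays = geom.n_views * geom.detector_rows * geom.detector_count
    if n_rays * n_vox > ORACLE_ELEMENT_CAP:
        raise ValueError(
            f"oracle instance too large: {n_rays} x {n_vox} elements "
            f"(cap {ORACLE_ELEMENT_CAP}); the oracle is for small instances")
    h, t_start, ns = _sampling(vol_template, geom)
    pitch = vol_template.pitch
    origin = np.asarray(vol_template.origin)
    sad, sdd = geom.source_axis_distance, geom.source_detector_distance
    dpitch = geom.detector_pixel_pitch
    ndet, nrow = geom.detector_count, geom.detector_rows
    ts = t_start + h * np.arange(ns)

    A = np.zeros((n_rays, n_vox))
    row = 0
    for a in geom.angles:
        ca, sa = math.cos(a), math.sin(a)
        if geom.mode == "fan2d":
            src = np.array([sad * ca, sad * sa])
            det_c = src - sdd * np.array([ca, sa])
            tang = np.array([-sa, ca])
            offsets = (np.arange(ndet) - (ndet - 1) / 2) * dpitch
            pixels = det_c[None, :] + offsets[:, None] * tang[None, :]
        else:
            src = np.array([sad * ca, sad * sa, 0.0])
            det_c = src - sdd * np.array([ca, sa, 0.0])
            tang = np.array([-sa, ca, 0.0])
            zdir = np.array([0.0, 0.0, 1.0])
            su = (np.arange(ndet) - (ndet - 1) / 2) * dpitch
            sr = (np.arange(nrow) - (nrow - 1) / 2) * dpitch
            pixels = (det_c[None, None, :] + sr[:, None, None] * zdir
                      + su[None, :, None] * tang).reshape(-1, 3)
        for pix in pixels:
            d = pix - src
            d /= np.linalg.norm(d)
            pts = src[None, :] + ts[:, None] * d[None, :]
            f = (pts - origin[None, :]) / pitch - 0.5
            base = np.floor(f).astype(np.int64)
            frac = f - base
            weights = np.full(ns, h)
            ndim = len(shape)
            for corner in np.ndindex(*([2] * ndim)):
                idx = base + np.asarray(corner)
                w = weights.copy()
                ok = np.ones(ns, dtype=bool)
                for ax in range(ndim):
                    ok &= (idx[:, ax] >= 0) & (idx[:, ax] < shape[ax])
                    w *= frac[:, ax] if corner[ax] else (1.0 - frac[:, ax])
                if not ok.any():
                    continue
                flat = np.ravel_multi_index(tuple(idx[ok].T), shape)
                np.add.at(A[row], flat, w[ok])
            row += 1
    return SystemMatrixOracle(A, geom, shape)


def subsample_views(proj: ProjectionData, n: int) -> ProjectionData:
    """Retrospective sparse-view subsampling: keep every ``n``-th view.

    Keeps views at indices 0, n, 2n, ... together with their angles, so a
    full scan of V views becomes a uniformly spaced scan of V/n views; ``n``
    must divide the view count exactly.
    """
    if n < 1:
        raise ValueError("subsampling factor must be a positive integer")
    if proj.n_views % n != 0:
        raise ValueError(
            f"subsampling factor {n} does not divide view count {proj.n_views}")
    if n == 1:
        return proj
    geom = replace(proj.geometry, angles=proj.geometry.angles[::n])
    return ProjectionData(proj.values[::n].copy(), geom,
                          photon_budget=proj.photon_budget,
                          negative_tolerance=proj.negative_tolerance)
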