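"""Quantitative comparison of vessel segmentations.

Three layers of comparison against a reference (full-view) segmentation:

* voxel classification — true positives, false positives and false
  negatives, with fractions normalised by the reference mask size;
* centerline geometry — a centerline is extracted from each mask
  (skeletonization, longest geodesic path, smoothing, resampling), control
  points are matched to the closest reference point in the L2 sense, and
  the mean 3D Euclidean distance between matched points is reported;
* diameters — at every control point a best-fit diameter is measured on
  the plane orthogonal to the local tangent, and the mean relative
  diameter error (percent of the reference diameter) is reported.

Differences between experimental conditions are tested with a two-tailed
Student's t-test (paired across subjects by default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage.morphology import skeletonize

from sparsect.segment import BinaryMask


@dataclass
class ClassificationCounts:
    """TP/FP/FN voxel counts of a test mask against a reference mask."""

    tp: int
    fp: int
    fn: int

    @property
    def reference_size(self) -> int:
        return self.tp + self.fn

    @property
    def test_size(self) -> int:
        return self.tp + self.fp

    @property
    def tp_fraction(self) -> float:
        return self.tp / self.reference_size

    @property
    def fp_fraction(self) -> float:
        return self.fp / self.reference_size

    @property
    def fn_fraction(self) -> float:
        return self.fn / self.reference_size


@dataclass
class Centerline:
    """Ordered control points (mm) with unit tangents and best-fit
    diameters (mm)."""

    points: np.ndarray
    tangents: np.ndarray
    diameters: np.ndarray

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.tangents = np.atleast_2d(np.asarray(self.tangents, dtype=float))
        self.diameters = np.asarray(self.diameters, dtype=float)
        if len(self.points) < 2:
            raise ValueError("a centerline needs at least two points")
        if np.any(np.linalg.norm(np.diff(self.points, axis=0), axis=1) == 0):
            raise ValueError("consecutive control points must be distinct")
        norms = np.linalg.norm(self.tangents, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("tangents must be unit vectors")
        if np.any(self.diameters <= 0):
            raise ValueError("diameters must be positive")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class TTestResult:
    statistic: float
    pvalue: float
    significant: bool  # at the 0.05 level


def classify_voxels(test: BinaryMask, ref: BinaryMask) -> ClassificationCounts:
    """Voxel overlap counts; TP+FN equals the reference size exactly."""
    t = np.asarray(test.values, dtype=bool)
    r = np.asarray(ref.values, dtype=bool)
    if t.shape != r.shape:
        raise ValueError("masks must share a shape")
    return ClassificationCounts(tp=int((t & r).sum()), fp=int((t & ~r).sum()),
                                fn=int((~t & r).sum()))


# ---------------------------------------------------------------------------
# Centerline extraction
# ---------------------------------------------------------------------------

def _skeleton_longest_path(skel: np.ndarray) -> np.ndarray:
    """Longest geodesic path through the voxel skeleton (indices).

    Builds the 26-connected (8 in 2D) adjacency graph of skeleton voxels,
    then runs two passes of Dijkstra (farthest node from an arbitrary
    start, then farthest from that) — exact on trees, best effort if the
    pruned skeleton still contains cycles.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import dijkstra

    coords = np.argwhere(skel)
    n = len(coords)
    index = {tuple(c): i for i, c in enumerate(coords)}
    ndim = skel.ndim
    rows, cols, weights = [], [], []
    offsets = [off for off in np.ndindex(*([3] * ndim))
               if any(o != 1 for o in off)]
    for i, c in enumerate(coords):
        for off in offsets:
            nb = tuple(c[ax] + off[ax] - 1 for ax in range(ndim))
            j = index.get(nb)
            if j is not None and j > i:
                w = math.sqrt(sum((off[ax] - 1) ** 2 for ax in range(ndim)))
                rows.append(i)
                cols.append(j)
                weights.append(w)
    if len(rows) >= n:
        warnings.warn("skeleton contains cycles; extracting a best-effort "
                      "longest path", stacklevel=3)
    graph = coo_matrix((weights, (rows, cols)), shape=(n, n)).tocsr()

    d0 = dijkstra(graph, directed=False, indices=0)
    reachable = np.isfinite(d0)
    if reachable.sum() < len(d0):
        warnings.warn("skeleton is disconnected; using the component of the "
                      "largest extent", stacklevel=3)
        d0[~reachable] = -np.inf
    a = int(np.argmax(d0))
    d1, pred = dijkstra(graph, directed=False, indices=a,
                        return_predecessors=True)
    d1[~np.isfinite(d1)] = -np.inf
    b = int(np.argmax(d1))
    path = [b]
    while path[-1] != a:
        p = pred[path[-1]]
        if p < 0:
            break
        path.append(int(p))
    return coords[path[::-1]]


def _moving_average(points: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return points
    half = window // 2
    out = np.empty_like(points)
    for i in range(len(points)):
        lo = max(0, i - half)
        hi = min(len(points), i + half + 1)
        out[i] = points[lo:hi].mean(axis=0)
    return out


def _resample_polyline(points: np.ndarray, spacing: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total <= spacing:
        return points[[0, -1]]
    n = int(math.floor(total / spacing)) + 1
    targets = np.linspace(0.0, total, n)
    return np.stack([np.interp(targets, arc, points[:, ax])
                     for ax in range(points.shape[1])], axis=1)


def extract_centerline(mask: BinaryMask, spacing: float | None = None,
                       smoothing_window: int = 5,
                       trim_points: int = 1,
                       diameter_mode: str = "area") -> Centerline:
    """Centerline of a tubular mask with per-point best-fit diameters.

    Skeletonizes the mask, walks the longest geodesic path, smooths it
    with a moving average, resamples control points at ``spacing``
    (default: two voxel pitches), computes tangents by central differences
    and measures a diameter at every control point.  ``trim_points``
    control points are dropped at each end, where tube end caps bias both
    tangents and cross sections.
    """
    values = np.asarray(mask.values, dtype=bool)
    if values.sum() < 2:
        raise ValueError("mask too small to carry a centerline")
    pitch = mask.pitch
    spacing = spacing if spacing is not None else 2.0 * pitch
    skel = skeletonize(values)
    if skel.sum() < 2:
        raise ValueError("skeleton degenerate; mask is not tubular")
    path = _skeleton_longest_path(skel)
    if len(path) < 2:
        raise ValueError("could not trace a path through the skeleton")
    pts = np.asarray(mask.origin)[None, :] + (path + 0.5) * pitch
    pts = _moving_average(pts, smoothing_window)
    pts = _resample_polyline(pts, spacing)
    if trim_points > 0 and len(pts) > 2 * trim_points + 1:
        pts = pts[trim_points:-trim_points]
    # central-difference tangents
    tans = np.gradient(pts, axis=0)
    tans /= np.linalg.norm(tans, axis=1, keepdims=True)
    diams = np.array([diameter_at_point(mask, p, t, mode=diameter_mode)
                      for p, t in zip(pts, tans)])
    return Centerline(pts, tans, diams)


def _perp_basis(tangent: np.ndarray) -> list:
    t = tangent / np.linalg.norm(tangent)
    if t.size == 2:
        return [np.array([-t[1], t[0]])]
    helper = np.array([1.0, 0.0, 0.0])
    if abs(t[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(t, helper)
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    return [u, v]


def diameter_at_point(mask: BinaryMask, point, tangent,
                      max_radius: float = 2.5, mode: str = "area") -> float:
    """Best-fit diameter of the cross-section orthogonal to ``tangent``.

    The mask is resampled on the orthogonal line (2D) or plane (3D) at
    half-voxel steps with linear interpolation; the connected cross-section
    containing the point is isolated and its diameter reported: the
    equivalent-area circle ``2*sqrt(area/pi)`` (``mode="area"``; in 2D the
    chord length) or a least-squares circle fit to the section boundary
    (``mode="circle-fit"``, 3D only).
    """
    point = np.asarray(point, dtype=float)
    tangent = np.asarray(tangent, dtype=float)
    pitch = mask.pitch
    step = pitch / 2.0
    basis = _perp_basis(tangent)
    n_half = int(math.ceil(max_radius / step))
    offsets = (np.arange(2 * n_half + 1) - n_half) * step
    if len(basis) == 1:
        sample_pts = point[None, :] + offsets[:, None] * basis[0][None, :]
        grid_shape = (len(offsets),)
    else:
        a, b = np.meshgrid(offsets, offsets, indexing="ij")
        sample_pts = (point[None, :] + a.ravel()[:, None] * basis[0][None, :]
                      + b.ravel()[:, None] * basis[1][None, :])
        grid_shape = a.shape
    idx = (sample_pts - np.asarray(mask.origin)[None, :]) / pitch - 0.5
    interp = ndimage.map_coordinates(mask.values.astype(float), idx.T,
                                     order=1, mode="constant", cval=0.0)
    inside = (interp >= 0.5).reshape(grid_shape)
    centre = tuple(n_half for _ in grid_shape)
    if not inside[centre]:
        raise ValueError("point is outside the mask")
    if len(grid_shape) == 1:
        lo = hi = n_half
        while lo > 0 and inside[lo - 1]:
            lo -= 1
        while hi < len(inside) - 1 and inside[hi + 1]:
            hi += 1
        return (hi - lo + 1) * step
    labels, _ = ndimage.label(inside, structure=np.ones((3, 3), dtype=bool))
    section = labels == labels[centre]
    if mode == "area":
        area = section.sum() * step * step
        return 2.0 * math.sqrt(area / math.pi)
    if mode == "circle-fit":
        eroded = ndimage.binary_erosion(section)
        boundary = np.argwhere(section & ~eroded) * step
        if len(boundary) < 3:
            area = section.sum() * step * step
            return 2.0 * math.sqrt(area / math.pi)
        # Kasa algebraic circle fit
        A = np.column_stack([2 * boundary, np.ones(len(boundary))])
        bvec = (boundary ** 2).sum(axis=1)
        sol, *_ = np.linalg.lstsq(A, bvec, rcond=None)
        cx, cy, c = sol
        return 2.0 * math.sqrt(c + cx * cx + cy * cy)
    raise ValueError(f"unknown diameter mode {mode!r}")


def match_points(c: Centerline, ref: Centerline) -> list:
    """For each control point of ``c``, the nearest reference control point
    (L2), ties broken toward the lower reference index.  Returns
    ``(index_in_c, index_in_ref)`` pairs."""
    diff = c.points[:, None, :] - ref.points[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    nearest = np.argmin(dist, axis=1)  # argmin takes the first (lowest) index
    return [(i, int(j)) for i, j in enumerate(nearest)]


def relative_diameter_error(c: Centerline, ref: Centerline) -> float:
    """Mean over matched pairs of ``|d - d_ref| / d_ref``, in percent."""
    pairs = match_points(c, ref)
    errs = [abs(c.diameters[i] - ref.diameters[j]) / ref.diameters[j]
            for i, j in pairs]
    return float(100.0 * np.mean(errs))


def centerline_distance(c: Centerline, ref: Centerline) -> float:
    """Mean Euclidean distance (mm) over matched control-point pairs."""
    pairs = match_points(c, ref)
    dists = [np.linalg.norm(c.points[i] - ref.points[j]) for i, j in pairs]
    return float(np.mean(dists))


def diameter_difference_um(relative_error_percent: float,
                           reference_diameter_mm: float) -> float:
    """Absolute diameter difference (micrometres) implied by a relative
    error, e.g. 13.7% of a 1.2 mm vessel -> 164 um."""
    return relative_error_percent / 100.0 * reference_diameter_mm * 1000.0


def compare_conditions(errors_condition, errors_reference,
                       paired: bool = True) -> TTestResult:
    """Two-tailed Student's t-test between per-subject error values.

    Paired across subjects by default (the same animals are measured under
    every condition); ``paired=False`` runs the two-sample test.  Identical
    paired samples (all differences zero) are reported as p = 1 with a
    warning rather than NaN.
    """
    a = np.asarray(errors_condition, dtype=float)
    b = np.asarray(errors_reference, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two subjects per group")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test needs equal group sizes")
        if np.allclose(a, b):
            warnings.warn("all paired differences are zero; reporting p = 1",
                          stacklevel=2)
            return TTestResult(0.0, 1.0, False)
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b)
    p = float(res.pvalue)
    return TTestResult(float(res.statistic), p, p < 0.05)
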