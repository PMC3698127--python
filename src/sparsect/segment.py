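"""Semi-automatic vascular segmentation.

The chain mirrors a contrast-enhanced vessel segmentation protocol: a small
seed volume of interest (VOI) placed inside the vessel provides intensity
statistics; the volume is thresholded to the interval
``[max(v_min, mean - 3*sigma), min(v_max, mean + 3*sigma)]``; the
preliminary mask is eroded by one voxel to detach noise speckle, region
grown from the VOI, dilated back by one voxel, and finally hole-filled.

All neighbourhood operations use the full 26-neighbourhood in 3D (8 in 2D)
and treat everything outside the grid as background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


class EmptyVoiError(ValueError):
    pass


class EmptyGrowthError(ValueError):
    """Seed region does not intersect the candidate mask."""


@dataclass
class VoiStats:
    """Intensity statistics inside a VOI (sample standard deviation)."""

    mean: float
    std: float
    minimum: float
    maximum: float

    def __post_init__(self):
        if not (self.minimum <= self.mean <= self.maximum):
            raise ValueError("VOI statistics violate min <= mean <= max")
        if self.std < 0:
            raise ValueError("standard deviation must be >= 0")


@dataclass
class BinaryMask:
    """Boolean grid aligned to a :class:`~sparsect.geometry.VolumeImage`."""

    values: np.ndarray
    voxel_pitch: float | tuple = 1.0
    origin: tuple | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim not in (2, 3):
            raise ValueError("mask must be 2D or 3D")
        pitch = np.atleast_1d(np.asarray(self.voxel_pitch, dtype=float))
        if pitch.size == 1:
            pitch = np.full(self.values.ndim, pitch[0])
        self.voxel_pitch = tuple(pitch)
        if self.origin is None:
            self.origin = tuple(-n * p / 2
                                for n, p in zip(self.values.shape, pitch))
        else:
            self.origin = tuple(float(o) for o in self.origin)

    @property
    def pitch(self) -> float:
        if len(set(self.voxel_pitch)) != 1:
            raise ValueError("operation requires an isotropic voxel grid")
        return self.voxel_pitch[0]

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def copy_with(self, values: np.ndarray) -> "BinaryMask":
        return BinaryMask(values, self.voxel_pitch, self.origin)


def _full_structure(ndim: int) -> np.ndarray:
    # 26-neighbourhood in 3D, 8-neighbourhood in 2D
    return np.ones((3,) * ndim, dtype=bool)


def voi_statistics(vol, voi: BinaryMask) -> VoiStats:
    """Mean, sample SD, min and max of the volume inside the VOI."""
    values = vol.values if hasattr(vol, "values") else np.asarray(vol, float)
    sel = values[np.asarray(voi.values, dtype=bool)]
    if sel.size == 0:
        raise EmptyVoiError("VOI contains no voxels")
    std = float(sel.std(ddof=1)) if sel.size > 1 else 0.0
    lo, hi = float(sel.min()), float(sel.max())
    # guard against summation round-off pushing the mean past min/max
    mean = min(max(float(sel.mean()), lo), hi)
    return VoiStats(mean=mean, std=std, minimum=lo, maximum=hi)


def threshold_segment(vol, stats: VoiStats) -> BinaryMask:
    """Threshold to ``[max(v_min, mean-3*sigma), min(v_max, mean+3*sigma)]``
    (both bounds inclusive)."""
    lower = max(stats.minimum, stats.mean - 3.0 * stats.std)
    upper = min(stats.maximum, stats.mean + 3.0 * stats.std)
    assert lower <= upper, "interval degenerate despite valid VOI statistics"
    values = vol.values if hasattr(vol, "values") else np.asarray(vol, float)
    mask = (values >= lower) & (values <= upper)
    pitch = getattr(vol, "voxel_pitch", 1.0)
    origin = getattr(vol, "origin", None)
    return BinaryMask(mask, pitch, origin)


def erode26(mask: BinaryMask) -> BinaryMask:
    """Erosion with the full 26-neighbourhood (8 in 2D); voxels outside the
    grid count as background, so the border shell is always removed."""
    out = ndimage.binary_erosion(mask.values,
                                 structure=_full_structure(mask.values.ndim),
                                 border_value=0)
    return mask.copy_with(out)


def dilate26(mask: BinaryMask) -> BinaryMask:
    """Dilation with the full 26-neighbourhood (8 in 2D)."""
    out = ndimage.binary_dilation(mask.values,
                                  structure=_full_structure(mask.values.ndim),
                                  border_value=0)
    return mask.copy_with(out)


def region_grow(candidate: BinaryMask, seed_voi: BinaryMask) -> BinaryMask:
    """Connected components of ``candidate`` (26-connectivity) reachable
    from the seed VOI."""
    cand = np.asarray(candidate.values, dtype=bool)
    seed = np.asarray(seed_voi.values, dtype=bool)
    if cand.shape != seed.shape:
        raise ValueError("seed and candidate masks must share a shape")
    if not np.any(cand & seed):
        raise EmptyGrowthError("seed VOI does not intersect the candidate mask")
    labels, _ = ndimage.label(cand, structure=_full_structure(cand.ndim))
    keep = np.unique(labels[cand & seed])
    out = np.isin(labels, keep) & cand
    return candidate.copy_with(out)


def fill_holes(mask: BinaryMask, mode: str = "literal") -> BinaryMask:
    """Fill holes in the mask.

    ``mode="literal"`` replaces each voxel with the OR of itself and its 26
    neighbours — a single dilation pass, which closes one-voxel holes but
    also adds a one-voxel shell and cannot fill wider cavities.
    ``mode="topological"`` flood-fills every background region not
    connected to the grid boundary.
    """
    if mode == "literal":
        return dilate26(mask)
    if mode == "topological":
        out = ndimage.binary_fill_holes(mask.values)
        return mask.copy_with(out)
    raise ValueError(f"unknown fill mode {mode!r}")


@dataclass
class SegmentationStages:
    """Intermediate masks of :func:`segment_vessels`, for inspection."""

    threshold: BinaryMask
    eroded: BinaryMask
    grown: BinaryMask
    dilated: BinaryMask
    filled: BinaryMask


def segment_vessels(vol, seed_voi: BinaryMask, fill_mode: str = "topological",
                    return_stages: bool = False):
    """Full chain: threshold -> erode -> region grow -> dilate -> fill holes.

    ``fill_mode`` defaults to topological hole filling: the literal
    OR-with-neighbours rule equals one extra dilation, which systematically
    inflates the boundary by a voxel shell; it remains available as
    ``fill_mode="literal"``.
    """
    stats = voi_statistics(vol, seed_voi)
    thresholded = threshold_segment(vol, stats)
    eroded = erode26(thresholded)
    grown = region_grow(eroded, seed_voi)
    dilated = dilate26(grown)
    filled = fill_holes(dilated, mode=fill_mode)
    if return_stages:
        return filled, SegmentationStages(thresholded, eroded, grown,
                                          dilated, filled)
    return filled
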