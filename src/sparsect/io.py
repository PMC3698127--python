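"""Volume, mask and sinogram file I/O.

Volumes go through SimpleITK as MetaImage (.mhd/.raw) or NIfTI
(.nii/.nii.gz), preserving per-axis voxel pitch and origin.  Note the axis
order convention: numpy axis 0 is the slowest-varying index, which ITK
stores as the last spacing component.  Sinograms are stored as flat
binary (float64 .raw) plus a JSON sidecar carrying shape, angles and the
scan geometry.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from sparsect.geometry import ProjectionData, ScanGeometry, VolumeImage
from sparsect.segment import BinaryMask

_VOLUME_SUFFIXES = (".mhd", ".mha", ".nii", ".nii.gz")


class FormatError(ValueError):
    pass


def _check_path(path: Path) -> Path:
    path = Path(path)
    name = path.name.lower()
    if not any(name.endswith(s) for s in _VOLUME_SUFFIXES):
        raise FormatError(f"unsupported volume format: {path.name} "
                          f"(expected one of {_VOLUME_SUFFIXES})")
    return path


def write_volume(vol: VolumeImage | BinaryMask, path) -> None:
    """Write a volume or mask (masks as 8-bit 0/1) with pitch and origin."""
    path = _check_path(path)
    arr = vol.values
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = sitk.GetImageFromArray(arr)
    # ITK spacing/origin are in x-fastest order: reverse the numpy axes
    img.SetSpacing(tuple(float(p) for p in vol.voxel_pitch[::-1]))
    centre0 = [o + 0.5 * p for o, p in zip(vol.origin, vol.voxel_pitch)]
    img.SetOrigin(tuple(float(c) for c in centre0[::-1]))
    sitk.WriteImage(img, str(path))


def read_volume(path, as_mask: bool = False) -> VolumeImage | BinaryMask:
    """Read a MetaImage/NIfTI volume back into a :class:`VolumeImage`
    (or :class:`BinaryMask` with ``as_mask``)."""
    path = _check_path(path)
    if not Path(path).exists():
        raise FormatError(f"no such volume: {path}")
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)
    pitch = tuple(img.GetSpacing())[::-1]
    centre0 = tuple(img.GetOrigin())[::-1]
    origin = tuple(c - 0.5 * p for c, p in zip(centre0, pitch))
    if as_mask:
        return BinaryMask(arr > 0, pitch, origin)
    return VolumeImage(arr.astype(float), pitch, origin)


def write_projections(proj: ProjectionData, stem) -> None:
    """Write a sinogram as ``<stem>.raw`` (float64) + ``<stem>.json``."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.asarray(proj.values, dtype="<f8").tofile(stem.with_suffix(".raw"))
    g = proj.geometry
    sidecar = {
        "shape": list(proj.values.shape),
        "dtype": "<f8",
        "mode": g.mode,
        "source_axis_distance": g.source_axis_distance,
        "source_detector_distance": g.source_detector_distance,
        "detector_pixel_pitch": g.detector_pixel_pitch,
        "detector_count": g.detector_count,
        "detector_rows": g.detector_rows,
        "angles": g.angles.tolist(),
        "photon_budget": proj.photon_budget,
        "negative_tolerance": proj.negative_tolerance,
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_projections(stem) -> ProjectionData:
    stem = Path(stem)
    meta_path = stem.with_suffix(".json")
    raw_path = stem.with_suffix(".raw")
    if not meta_path.exists() or not raw_path.exists():
        raise FormatError(f"missing sinogram pair {raw_path} / {meta_path}")
    meta = json.loads(meta_path.read_text())
    geom = ScanGeometry(
        mode=meta["mode"],
        source_axis_distance=meta["source_axis_distance"],
        source_detector_distance=meta["source_detector_distance"],
        detector_pixel_pitch=meta["detector_pixel_pitch"],
        detector_count=meta["detector_count"],
        angles=np.asarray(meta["angles"]),
        detector_rows=meta.get("detector_rows", 1),
    )
    values = np.fromfile(raw_path, dtype=meta["dtype"]).reshape(meta["shape"])
    return ProjectionData(values, geom, photon_budget=meta.get("photon_budget"),
                          negative_tolerance=meta.get("negative_tolerance", 0.0))
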