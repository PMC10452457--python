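"""File I/O: NIfTI volumes, JSON point/axis files, CSV reports.

Volumes are read and written with nibabel, preserving the stored affine
exactly.  Point files are small JSON documents with physical-mm coordinates
in the image's affine frame; voxel-index input is deliberately not accepted
(avoids 0/1-based ambiguity).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from ..core import ValidationError, VolumeGrid
from ..geometry import Axis


def read_mask(path: str | Path, *, binary: bool = True) -> VolumeGrid:
    """Load a NIfTI volume as a :class:`VolumeGrid`.

    With ``binary=True`` values must be {0,1}; otherwise integer labels 0-17
    are required.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3D volume, got shape {data.shape}")
    if not np.allclose(data, np.round(data)):
        raise ValidationError(f"{path}: volume contains non-integer values")
    data = np.round(data).astype(np.int16)
    grid = VolumeGrid(data, img.affine)
    if binary:
        grid.require_binary()
        grid = grid.with_data(data.astype(bool))
    else:
        bad = np.unique(data[(data < 0) | (data > 17)])
        if bad.size:
            raise ValidationError(f"{path}: labels outside 0-17: {bad}")
    return grid


def write_labels(grid: VolumeGrid, path: str | Path) -> None:
    """Write a mask/label grid as integer NIfTI with its affine unchanged."""
    data = np.asarray(grid.data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    else:
        data = data.astype(np.int16)
    nib.save(nib.Nifti1Image(data, grid.affine), str(path))


def read_point_file(path: str | Path) -> np.ndarray:
    """Read a JSON point file: ``{"point": [x,y,z]}`` or ``{"points": [...]}``.

    Returns shape (3,) for a single point, (N,3) for a points list.  All
    coordinates are physical mm.
    """
    doc = json.loads(Path(path).read_text())
    if "point" in doc:
        p = np.asarray(doc["point"], dtype=float)
        if p.shape != (3,):
            raise ValidationError(f"{path}: 'point' must be one mm-triple")
        return p
    if "points" in doc:
        pts = np.asarray(doc["points"], dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 1:
            raise ValidationError(f"{path}: 'points' must be a list of mm-triples")
        return pts
    raise ValidationError(f"{path}: expected a 'point' or 'points' key")


def write_point_file(point: np.ndarray, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"point": [float(x) for x in np.asarray(point)]}, indent=2) + "\n"
    )


def read_axis_file(path: str | Path) -> Axis:
    """Read an axis: either serialized fields or a two-point ``points`` list
    (first point basal, second apical)."""
    doc = json.loads(Path(path).read_text())
    if "direction" in doc:
        return Axis.from_dict(doc)
    if "points" in doc:
        pts = np.asarray(doc["points"], dtype=float)
        if pts.shape != (2, 3):
            raise ValidationError(f"{path}: axis 'points' must be two mm-triples")
        return Axis.from_two_points(pts[0], pts[1])
    raise ValidationError(f"{path}: not a recognizable axis file")


def write_report(rows: list[dict], path: str | Path) -> None:
    """Write a plain CSV report with a header row."""
    pd.DataFrame(rows).to_csv(path, index=False)


# -- experimental: DICOM RT-STRUCT import ------------------------------
def contours_to_mask(
    contours_mm: list[np.ndarray], reference: VolumeGrid
) -> VolumeGrid:
    """Rasterize planar closed contours (physical-mm polygons) onto a grid.

    Each contour is assigned to its nearest grid slice along the third array
    axis and filled by even-odd polygon rasterization in voxel coordinates.
    This backs the experimental RT-STRUCT import.
    """
    from matplotlib.path import Path as MplPath

    out = np.zeros(reference.shape, dtype=bool)
    ny, nx = reference.shape[0], reference.shape[1]
    grid_ij = np.stack(
        np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij"), axis=-1
    ).reshape(-1, 2)
    for poly in contours_mm:
        vox = reference.world_to_voxel(np.asarray(poly, float))
        k = int(np.round(vox[:, 2].mean()))
        if not 0 <= k < reference.shape[2]:
            continue
        path = MplPath(vox[:, :2])
        inside = path.contains_points(grid_ij).reshape(ny, nx)
        out[:, :, k] |= inside
    return reference.with_data(out)


def read_rtstruct(path: str | Path, roi_name: str, reference: VolumeGrid) -> VolumeGrid:
    """EXPERIMENTAL: load one ROI of a DICOM RT-STRUCT as a binary mask.

    Requires ``pydicom`` (not a hard dependency).
    """
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ValidationError(
            "RT-STRUCT import requires the optional 'pydicom' package"
        ) from exc
    ds = pydicom.dcmread(str(path))
    rois = {r.ROIName: r.ROINumber for r in ds.StructureSetROISequence}
    if roi_name not in rois:
        raise ValidationError(f"ROI {roi_name!r} not in {sorted(rois)}")
    number = rois[roi_name]
    contours: list[np.ndarray] = []
    for rc in ds.ROIContourSequence:
        if rc.ReferencedROINumber != number:
            continue
        for cont in getattr(rc, "ContourSequence", []):
            pts = np.asarray(cont.ContourData, float).reshape(-1, 3)
            contours.append(pts)
    if not contours:
        raise ValidationError(f"ROI {roi_name!r} has no contours")
    return contours_to_mask(contours, reference)
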