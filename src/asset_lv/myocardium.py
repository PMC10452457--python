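"""Myocardial shell construction: the standardized inner ring on the LV.

The cavity is the Euclidean erosion of the LV mask by the wall thickness,
computed anisotropy-aware via a distance transform in physical mm; the
myocardium is the set difference.  An optional plane cut perpendicular to the
long axis removes the basal (mitral-valve) cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .core import EmptyMaskError, ValidationError, VolumeGrid, Warnings
from .geometry import Axis

DEFAULT_THICKNESS_MM = 8.0


@dataclass
class MyocardiumSet:
    """Myocardial shell + cavity derived from one LV mask.

    Invariant: ``myo`` and ``cavity`` are disjoint and (before any basal cap
    removal) their union is the input LV mask.
    """

    myo: VolumeGrid
    cavity: VolumeGrid
    thickness_mm: float
    basal_cut_t: float | None = None
    warnings: Warnings = field(default_factory=Warnings)


def make_myocardium(
    lv_mask: VolumeGrid, thickness_mm: float = DEFAULT_THICKNESS_MM
) -> MyocardiumSet:
    """Split an LV mask into a shell of physical thickness ``thickness_mm``
    and the remaining cavity.

    The cavity is the set of mask voxels whose Euclidean distance (mm, using
    the grid spacing) to the background is at least ``thickness_mm``; the
    shell is everything else in the mask.  A thickness that empties the
    cavity sets a warning on the result rather than raising.
    """
    if thickness_mm <= 0:
        raise ValidationError("thickness_mm must be > 0")
    lv_mask.require_binary()
    mask = lv_mask.data.astype(bool)
    if not mask.any():
        raise EmptyMaskError("LV mask is empty")
    dist = ndi.distance_transform_edt(mask, sampling=lv_mask.spacing)
    cavity = dist >= thickness_mm
    myo = mask & ~cavity
    result = MyocardiumSet(
        myo=lv_mask.with_data(myo),
        cavity=lv_mask.with_data(cavity),
        thickness_mm=float(thickness_mm),
    )
    if not cavity.any():
        result.warnings.add(
            f"thickness {thickness_mm} mm leaves an empty cavity; "
            "shell equals the whole LV mask"
        )
    return result


def remove_basal_cap(myoset: MyocardiumSet, axis: Axis, t_base: float) -> MyocardiumSet:
    """Drop shell voxels with axial coordinate below ``t_base``.

    The cut plane is perpendicular to the (base->apex oriented) axis; the
    cavity is untouched.  ``t_base`` must lie within the axis extent.
    """
    if not axis.t_min <= t_base <= axis.t_max:
        raise ValidationError(
            f"t_base={t_base} outside the axis extent "
            f"[{axis.t_min:.2f}, {axis.t_max:.2f}]"
        )
    myo = myoset.myo.data.astype(bool)
    ijk = np.argwhere(myo)
    if ijk.size:
        t = axis.axial_coord(myoset.myo.voxel_to_world(ijk))
        drop = ijk[t < t_base]
        myo = myo.copy()
        myo[tuple(drop.T)] = False
    return replace(
        myoset,
        myo=myoset.myo.with_data(myo),
        basal_cut_t=float(t_base),
    )
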