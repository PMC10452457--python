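"""Synthetic LV phantom with analytic ground truth.

The phantom is a half prolate spheroid, open (flat-cut) at the base plane:
in its local frame the long axis runs along +z from the base plane (z = 0)
to the apex tip (z = ``long_axis_mm``); the epicardial surface is the
ellipsoid with transverse semi-axis ``epicardial_radius_mm`` and axial
semi-axis ``long_axis_mm``; the endocardial surface is the same ellipsoid
with both semi-axes reduced by ``wall_mm`` and the cavity open at the base,
leaving a solid apex cap.

For the default (identity) orientation the voxel grid starts exactly at the
base plane, so the mask has no background below the base — mirroring a
curated clinical LV whose basal cap has been removed — and a distance
transform "sees" only the epicardial surface, as intended.

:func:`analytic_labels` is an *independent oracle*: every voxel is labeled in
closed form from its known cylindrical coordinates about the true axis.  It
deliberately shares no code with the pipeline's axis estimation, shell
construction, or voxel assignment (the AHA label tables are restated here as
literals), so pipeline/oracle agreement is evidential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ValidationError, VolumeGrid
from .geometry import Axis

# AHA label order with increasing azimuth from the RV reference direction.
# Restated literally (not imported) to keep this oracle independent.
_ORACLE_BASAL = (1, 6, 5, 4, 3, 2)
_ORACLE_MID = (7, 12, 11, 10, 9, 8)
_ORACLE_APICAL = (13, 16, 15, 14)  # first sector starts at -15 degrees


@dataclass
class PhantomSpec:
    """Parameters of the synthetic LV (all lengths in mm)."""

    long_axis_mm: float = 90.0
    epicardial_radius_mm: float = 40.0
    wall_mm: float = 8.0
    base_cut_fraction: float = 0.0
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.5)
    rotation: np.ndarray | None = None  # 4x4 rigid local->world, default identity
    rv_azimuth_deg: float = 0.0
    jitter_seed: int | None = None
    jitter_amp_mm: float = 0.5
    margin_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.wall_mm <= 0 or self.wall_mm >= self.epicardial_radius_mm:
            raise ValidationError("wall_mm must lie in (0, epicardial_radius_mm)")
        if self.long_axis_mm <= self.wall_mm:
            raise ValidationError("long_axis_mm must exceed wall_mm")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValidationError("spacing must be positive")
        if not 0.0 <= self.base_cut_fraction < 1.0:
            raise ValidationError("base_cut_fraction must lie in [0, 1)")
        if self.rotation is not None:
            R = np.asarray(self.rotation, float)
            if R.shape != (4, 4):
                raise ValidationError("rotation must be a 4x4 homogeneous matrix")
            if not np.allclose(R[:3, :3] @ R[:3, :3].T, np.eye(3), atol=1e-8):
                raise ValidationError("rotation block must be orthonormal")
            object.__setattr__(self, "rotation", R)

    @property
    def transform(self) -> np.ndarray:
        return np.eye(4) if self.rotation is None else self.rotation

    @property
    def is_identity(self) -> bool:
        return self.rotation is None or np.allclose(self.rotation, np.eye(4), atol=1e-12)

    @property
    def base_cut_z(self) -> float:
        return self.base_cut_fraction * self.long_axis_mm


@dataclass
class PhantomResult:
    lv_mask: VolumeGrid
    rv_point: np.ndarray
    truth_labels: VolumeGrid
    true_axis: Axis
    spec: PhantomSpec = field(repr=False, default=None)  # type: ignore[assignment]


# ----------------------------------------------------------------------
def _phantom_affine(spec: PhantomSpec) -> tuple[tuple[int, int, int], np.ndarray]:
    """Deterministic grid (shape, affine) covering the phantom.

    Identity orientation: the grid's first z-plane of voxel centers sits half
    a voxel above the base plane and there is no padding below it; margins
    elsewhere.  Rotated: axis-aligned world bounding box of the transformed
    shape with margins on all sides.
    """
    a = spec.epicardial_radius_mm
    c = spec.long_axis_mm
    m = spec.margin_mm
    sx, sy, sz = spec.spacing_mm
    if spec.is_identity:
        lo = np.array([-(a + m), -(a + m), spec.base_cut_z])
        hi = np.array([a + m, a + m, c + m])
    else:
        corners = np.array(
            [
                [px, py, pz, 1.0]
                for px in (-a, a)
                for py in (-a, a)
                for pz in (spec.base_cut_z, c)
            ]
        )
        world = corners @ spec.transform.T
        lo = world[:, :3].min(axis=0) - m
        hi = world[:, :3].max(axis=0) + m
    spacing = np.array([sx, sy, sz])
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / spacing[i])) for i in range(3))
    affine = np.diag([sx, sy, sz, 1.0])
    affine[:3, 3] = lo + spacing / 2.0
    return shape, affine  # voxel (0,0,0) center = lo + spacing/2


def _local_coords(spec: PhantomSpec, shape, affine) -> tuple[np.ndarray, ...]:
    """Local-frame coordinates (x, y, z) of every voxel center, each 3D."""
    idx = np.indices(shape, dtype=float)
    world = np.einsum(
        "ab,b...->a...", affine[:3, :3], idx
    ) + affine[:3, 3][:, None, None, None]
    inv = np.linalg.inv(spec.transform)
    local = np.einsum("ab,b...->a...", inv[:3, :3], world) + inv[:3, 3][
        :, None, None, None
    ]
    return local[0], local[1], local[2]


def _outer_implicit(spec: PhantomSpec, x, y, z) -> np.ndarray:
    a = spec.epicardial_radius_mm
    c = spec.long_axis_mm
    return (x * x + y * y) / (a * a) + (z * z) / (c * c)


def make_lv_phantom(spec: PhantomSpec | None = None) -> PhantomResult:
    """Voxelize the phantom; return mask, RV point, truth labels, true axis.

    Deterministic for a given spec (and ``jitter_seed``).  The RV-insertion
    point sits on the epicardial surface at mid-level at the requested
    azimuth.  Optional seeded surface jitter (smooth, <= ``jitter_amp_mm``)
    perturbs the voxelized epicardial surface only; the truth labels stay
    analytic.
    """
    spec = spec or PhantomSpec()
    shape, affine = _phantom_affine(spec)
    x, y, z = _local_coords(spec, shape, affine)

    f_out = _outer_implicit(spec, x, y, z)
    threshold = np.ones_like(f_out)
    if spec.jitter_seed is not None:
        from scipy import ndimage as ndi

        rng = np.random.default_rng(spec.jitter_seed)
        noise = ndi.gaussian_filter(rng.standard_normal(shape), sigma=3.0)
        noise /= max(np.abs(noise).max(), 1e-12)
        # |grad f| ~ 2/a near the equatorial surface: eps -> ~eps*a/2 mm shift
        threshold = 1.0 + noise * (2.0 * spec.jitter_amp_mm / spec.epicardial_radius_mm)
    lv = (f_out <= threshold) & (z >= spec.base_cut_z)

    lv_mask = VolumeGrid(lv, affine)

    # RV-insertion point: epicardial surface, mid-level, requested azimuth
    c = spec.long_axis_mm
    a = spec.epicardial_radius_mm
    z_mid = 0.45 * c
    rho = a * np.sqrt(max(1.0 - (z_mid / c) ** 2, 0.0))
    az = np.radians(spec.rv_azimuth_deg)
    rv_local = np.array([rho * np.cos(az), rho * np.sin(az), z_mid, 1.0])
    rv_point = (spec.transform @ rv_local)[:3]

    base_local = np.array([0.0, 0.0, spec.base_cut_z, 1.0])
    dir_local = np.array([0.0, 0.0, 1.0, 0.0])
    true_axis = Axis(
        anchor=(spec.transform @ base_local)[:3],
        direction=(spec.transform @ dir_local)[:3],
        t_min=0.0,
        t_max=c - spec.base_cut_z,
    )

    truth = analytic_labels(spec)
    return PhantomResult(lv_mask, rv_point, truth, true_axis, spec)


def analytic_labels(spec: PhantomSpec | None = None) -> VolumeGrid:
    """Closed-form truth label map on the phantom grid (independent oracle).

    Every voxel is classified from its local cylindrical coordinates: the
    analytic cavity is the wall-offset inner spheroid (open at the base,
    solid apex cap); the myocardium is the outer half-spheroid minus the
    cavity.  Region boundaries trisect base-to-cavity-tip, with the apex
    distal to the cavity tip; sectors are 60-degree (basal/mid, from the RV
    azimuth) and 90-degree (apical, from -15 degrees).
    """
    spec = spec or PhantomSpec()
    shape, affine = _phantom_affine(spec)
    x, y, z = _local_coords(spec, shape, affine)

    a = spec.epicardial_radius_mm
    c = spec.long_axis_mm
    w = spec.wall_mm
    ai, ci = a - w, c - w

    outer = (_outer_implicit(spec, x, y, z) <= 1.0) & (z >= spec.base_cut_z)
    cavity = ((x * x + y * y) / (ai * ai) + (z * z) / (ci * ci) <= 1.0) & (
        z >= spec.base_cut_z
    )
    myo = outer & ~cavity
    if not myo.any() or not cavity.any():
        raise ValidationError("degenerate phantom: empty shell or cavity")

    t = z  # axial coordinate about the true axis (anchor at base center)
    t0 = float(t[myo].min())
    t3 = float(t[cavity].max())  # cavity tip
    t4 = float(t[myo].max())
    span = (t3 - t0) / 3.0
    t1, t2 = t0 + span, t0 + 2.0 * span

    theta = (np.degrees(np.arctan2(y, x)) - spec.rv_azimuth_deg) % 360.0

    labels = np.zeros(shape, dtype=np.int16)
    region = np.digitize(t, (t1, t2, t3))  # 0 basal, 1 mid, 2 apical, 3 apex
    basal = np.take(_ORACLE_BASAL, np.clip((theta // 60.0).astype(int), 0, 5))
    mid = np.take(_ORACLE_MID, np.clip((theta // 60.0).astype(int), 0, 5))
    apical = np.take(
        _ORACLE_APICAL, np.clip((((theta + 15.0) % 360.0) // 90.0).astype(int), 0, 3)
    )
    labels[myo & (region == 0)] = basal[myo & (region == 0)]
    labels[myo & (region == 1)] = mid[myo & (region == 1)]
    labels[myo & (region == 2)] = apical[myo & (region == 2)]
    labels[myo & (region == 3)] = 17
    return VolumeGrid(labels, affine)
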