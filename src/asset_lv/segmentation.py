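"""AHA 17-segment assignment on the myocardial shell.

Stages:

* :func:`region_planes` — three short-axis planes perpendicular to the long
  axis split the shell into basal / mid / apical regions of equal axial
  length, plus the apex cap distal to the cavity tip.
* :class:`SectorScheme` / :func:`sector_label` — fixed-angle azimuthal
  sectorization anchored at the RV-insertion direction: six 60-degree sectors
  for basal and mid, four 90-degree sectors (boundaries at -15/75/165/255
  degrees) for apical, one apex segment.
* :func:`assign_segments` — per-voxel label assignment by cylindrical
  coordinates about the axis (voxel centers, half-open intervals).
* :func:`close_segments` — per-segment morphological closing with a Euclidean
  ball, conflict resolution preserving the partition of the shell.
* :func:`run_asset` — the end-to-end pipeline.

Angular convention (documented, configurable): azimuth 0 points at the RV
insertion; positive azimuth follows the right-hand rule about the base->apex
direction so that increasing azimuth runs anterior -> anterolateral -> ... ->
anteroseptal.  ``flip_rotation`` inverts the chirality for datasets whose
anatomy disagrees.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .core import UndefinedAzimuthError, ValidationError, VolumeGrid, Warnings
from .geometry import Axis, compute_plax, orient_base_to_apex
from .io_cli.config import RunConfig
from .myocardium import MyocardiumSet, make_myocardium, remove_basal_cap

SEGMENT_NAMES: dict[int, str] = {
    1: "basal anterior",
    2: "basal anteroseptal",
    3: "basal inferoseptal",
    4: "basal inferior",
    5: "basal inferolateral",
    6: "basal anterolateral",
    7: "mid anterior",
    8: "mid anteroseptal",
    9: "mid inferoseptal",
    10: "mid inferior",
    11: "mid inferolateral",
    12: "mid anterolateral",
    13: "apical anterior",
    14: "apical septal",
    15: "apical inferior",
    16: "apical lateral",
    17: "apex",
}

REGIONS = ("basal", "mid", "apical", "apex")

# label order with increasing azimuth from the RV-insertion reference
_BASAL_ORDER = (1, 6, 5, 4, 3, 2)
_MID_ORDER = (7, 12, 11, 10, 9, 8)
_APICAL_ORDER = (13, 16, 15, 14)  # starting at -15 degrees
_APICAL_OFFSET_DEG = 15.0  # apical boundaries sit at -15, 75, 165, 255


@dataclass(frozen=True)
class RegionPlanes:
    """Axial positions (mm) of the region boundaries along the long axis.

    ``t0`` basal extent, ``t1`` basal|mid, ``t2`` mid|apical, ``t3``
    apical|apex, ``t4`` apex tip.  The three proximal spans are equal.
    """

    t0: float
    t1: float
    t2: float
    t3: float
    t4: float

    def __post_init__(self) -> None:
        ts = (self.t0, self.t1, self.t2, self.t3)
        if not all(a < b for a, b in zip(ts, ts[1:])) or not self.t3 <= self.t4:
            raise ValidationError(f"region planes not ordered: {self}")
        spans = (self.t1 - self.t0, self.t2 - self.t1, self.t3 - self.t2)
        if max(spans) - min(spans) > 1e-6:
            raise ValidationError(f"basal/mid/apical spans unequal: {spans}")

    def region_of(self, t: np.ndarray) -> np.ndarray:
        """0 basal, 1 mid, 2 apical, 3 apex; half-open, last interval closed."""
        return np.digitize(np.asarray(t, float), (self.t1, self.t2, self.t3))

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in ("t0", "t1", "t2", "t3", "t4")}


@dataclass(frozen=True)
class SectorScheme:
    """Azimuthal sector boundaries and the mapping to AHA labels 1-17."""

    ref_dir: np.ndarray
    flip_rotation: bool = False
    basal_mid_boundaries: tuple[float, ...] = (0.0, 60.0, 120.0, 180.0, 240.0, 300.0)
    apical_boundaries: tuple[float, ...] = (-15.0, 75.0, 165.0, 255.0)

    def __post_init__(self) -> None:
        d = np.asarray(self.ref_dir, float)
        n = np.linalg.norm(d)
        if n < 1e-9:
            raise ValidationError("ref_dir must be nonzero")
        object.__setattr__(self, "ref_dir", d / n)

    def label(self, region: str, theta_deg: float | np.ndarray):
        return sector_label(region, theta_deg)

    def segment_boundaries(self, label: int) -> tuple[float, float]:
        """Azimuthal interval [lo, hi) of a non-apex segment, degrees from
        the RV reference (lo may be negative for the wrap-around sector)."""
        if label == 17:
            raise ValidationError("the apex segment has no azimuthal boundaries")
        if label in _BASAL_ORDER:
            k = _BASAL_ORDER.index(label)
        elif label in _MID_ORDER:
            k = _MID_ORDER.index(label)
        else:
            k = _APICAL_ORDER.index(label)
            lo = self.apical_boundaries[k]
            return (lo, lo + 90.0)
        lo = self.basal_mid_boundaries[k]
        return (lo, lo + 60.0)

    def to_dict(self) -> dict:
        return {
            "ref_dir": [float(x) for x in self.ref_dir],
            "flip_rotation": self.flip_rotation,
            "basal_mid_boundaries": list(self.basal_mid_boundaries),
            "apical_boundaries": list(self.apical_boundaries),
        }


def sector_label(region: str, theta_deg: float | np.ndarray):
    """AHA label for a voxel in ``region`` at azimuth ``theta_deg``.

    Total function: any finite angle is wrapped to [0, 360).  Scalar in,
    scalar out; array in, array out.
    """
    if region not in REGIONS:
        raise ValidationError(f"unknown region {region!r}")
    theta = np.asarray(theta_deg, dtype=float) % 360.0
    if region == "apex":
        out = np.full(theta.shape, 17, dtype=np.int16)
    elif region in ("basal", "mid"):
        order = np.asarray(_BASAL_ORDER if region == "basal" else _MID_ORDER)
        out = order[np.clip((theta // 60.0).astype(int), 0, 5)]
    else:  # apical
        shifted = (theta + _APICAL_OFFSET_DEG) % 360.0
        out = np.asarray(_APICAL_ORDER)[np.clip((shifted // 90.0).astype(int), 0, 3)]
    return int(out) if np.isscalar(theta_deg) else out.astype(np.int16)


@dataclass
class SegmentationResult:
    """Final 17-label map plus full provenance of how it was produced."""

    labels: VolumeGrid
    axis: Axis
    planes: RegionPlanes
    scheme: SectorScheme
    config: dict = field(default_factory=dict)
    warnings: Warnings = field(default_factory=Warnings)
    timings_s: dict = field(default_factory=dict)

    def present_labels(self) -> list[int]:
        vals = np.unique(self.labels.data)
        return [int(v) for v in vals if v != 0]


# ----------------------------------------------------------------------
def region_planes(
    myoset: MyocardiumSet,
    axis: Axis,
    apex_rule: str | tuple[str, float] = "cavity_tip",
) -> RegionPlanes:
    """Place the three short-axis planes along the base->apex axis.

    ``t0``/``t4`` are the axial extremes of the shell.  Under the default
    ``cavity_tip`` rule the apical|apex boundary ``t3`` is the axial tip of
    the cavity; under ``("fraction", f)`` it is ``t0 + (1-f)(t4-t0)``.  The
    planes ``t1``/``t2`` trisect ``[t0, t3]`` into equal spans.
    """
    myo_pts = myoset.myo.mask_world_coords()
    if myo_pts.shape[0] == 0:
        raise ValidationError("myocardium is empty")
    t_myo = axis.axial_coord(myo_pts)
    t0, t4 = float(t_myo.min()), float(t_myo.max())

    if apex_rule == "cavity_tip":
        cav_pts = myoset.cavity.mask_world_coords()
        if cav_pts.shape[0] == 0:
            raise ValidationError(
                "cavity is empty; the cavity_tip apex rule is undefined "
                "(use apex_rule=('fraction', f))"
            )
        t3 = float(axis.axial_coord(cav_pts).max())
    elif isinstance(apex_rule, tuple) and apex_rule[0] == "fraction":
        f = float(apex_rule[1])
        if not 0.0 < f < 1.0:
            raise ValidationError("apex fraction must lie in (0, 1)")
        t3 = t0 + (1.0 - f) * (t4 - t0)
    else:
        raise ValidationError(f"unknown apex_rule {apex_rule!r}")

    if t3 <= t0:
        raise ValidationError(f"apex boundary t3={t3} not above base t0={t0}")
    t3 = min(t3, t4)
    span = (t3 - t0) / 3.0
    return RegionPlanes(t0, t0 + span, t0 + 2.0 * span, t3, t4)


def _azimuths(
    points: np.ndarray, axis: Axis, ref_dir: np.ndarray, flip_rotation: bool
) -> np.ndarray:
    """Vectorized azimuth; on-axis points get 0 (caller decides if that matters)."""
    e2 = np.cross(axis.direction, ref_dir)
    if flip_rotation:
        e2 = -e2
    v = axis.radial_vector(points)
    theta = np.degrees(np.arctan2(v @ e2, v @ ref_dir))
    theta = theta % 360.0
    theta[np.linalg.norm(v, axis=1) <= 1e-6] = 0.0
    return theta


def reference_direction(
    axis: Axis, rv_point: np.ndarray, warnings: Warnings | None = None
) -> np.ndarray:
    """Unit azimuth-zero direction: orthogonal component of rv_point - axis."""
    rv_point = np.asarray(rv_point, float)
    v = axis.radial_vector(rv_point)[0]
    n = float(np.linalg.norm(v))
    if n <= 1e-6:
        raise UndefinedAzimuthError(
            "RV-insertion point lies on the long axis; reference azimuth undefined"
        )
    t_rv = float(axis.axial_coord(rv_point)[0])
    if warnings is not None and not axis.t_min <= t_rv <= axis.t_max:
        warnings.add(
            f"RV-insertion point projects outside the axial extent "
            f"(t={t_rv:.1f} mm, extent [{axis.t_min:.1f}, {axis.t_max:.1f}]); "
            "only its azimuth is used"
        )
    return v / n


def assign_segments(
    myoset: MyocardiumSet,
    axis: Axis,
    rv_point: np.ndarray,
    planes: RegionPlanes,
    scheme: SectorScheme | None = None,
    *,
    flip_rotation: bool = False,
    restrict_to: np.ndarray | None = None,
) -> SegmentationResult:
    """Label every shell voxel with its AHA segment (1-17).

    Voxels are classified by their center coordinate: axial position selects
    the region against ``planes`` (half-open intervals, last closed), azimuth
    about the axis selects the sector.  Nonzero labels exactly partition the
    shell.  ``restrict_to`` (boolean array) limits assignment to a subset of
    shell voxels (used by the surface mode).
    """
    warnings = Warnings()
    if scheme is None:
        ref = reference_direction(axis, rv_point, warnings)
        scheme = SectorScheme(ref_dir=ref, flip_rotation=flip_rotation)

    myo = myoset.myo.data.astype(bool)
    support = myo if restrict_to is None else (myo & restrict_to)
    ijk = np.argwhere(support)
    labels = np.zeros(myo.shape, dtype=np.int16)
    if ijk.size:
        pts = myoset.myo.voxel_to_world(ijk)
        t = axis.axial_coord(pts)
        theta = _azimuths(pts, axis, scheme.ref_dir, scheme.flip_rotation)
        region_idx = planes.region_of(t)
        # voxels below t0 or above t4 cannot occur when planes came from this
        # shell; clamp defensively for externally supplied planes
        region_idx = np.clip(region_idx, 0, 3)
        vox_labels = np.empty(len(ijk), dtype=np.int16)
        for r_idx, r_name in enumerate(REGIONS):
            sel = region_idx == r_idx
            if sel.any():
                vox_labels[sel] = sector_label(r_name, theta[sel])
        labels[tuple(ijk.T)] = vox_labels

    result = SegmentationResult(
        labels=myoset.myo.with_data(labels),
        axis=axis,
        planes=planes,
        scheme=scheme,
        warnings=warnings,
    )
    if restrict_to is None:
        missing = sorted(set(range(1, 18)) - set(result.present_labels()))
        for m in missing:
            warnings.add(f"segment {m} ({SEGMENT_NAMES[m]}) has zero voxels")
    return result


def _ball_structure(radius_mm: float, spacing: np.ndarray) -> np.ndarray:
    """Euclidean ball of ``radius_mm`` as a voxel structuring element."""
    half = np.maximum(np.floor(radius_mm / spacing).astype(int), 0)
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) * s for h, s in zip(half, spacing)], indexing="ij"
    )
    r2 = sum(g * g for g in grids)
    return r2 <= radius_mm**2 + 1e-9


def close_segments(
    result: SegmentationResult,
    radius_mm: float = 2.0,
    myo: np.ndarray | None = None,
) -> SegmentationResult:
    """Morphologically close each segment (dilation then erosion, Euclidean
    ball) and re-intersect with the shell.

    ``myo`` is the shell support the closed segments may claim (defaults to
    the nonzero support of the input labels).  Conflict policy keeps the
    output a partition: voxels claimed by several closed segments revert to
    their pre-closing label; voxels claimed by none keep theirs.
    """
    if radius_mm < 0:
        raise ValidationError("radius_mm must be >= 0")
    pre = result.labels.data
    if radius_mm == 0:
        return result
    spacing = result.labels.spacing
    structure = _ball_structure(radius_mm, spacing)
    support = (pre > 0) if myo is None else np.asarray(myo).astype(bool)
    claims = np.zeros(pre.shape, dtype=np.int8)
    claimed_label = np.zeros(pre.shape, dtype=np.int16)
    for lab in np.unique(pre[pre > 0]):
        closed = ndi.binary_closing(pre == lab, structure=structure) & support
        claims += closed
        claimed_label[closed] = lab
    new = np.where((claims == 1) & support, claimed_label, pre)
    out = SegmentationResult(
        labels=result.labels.with_data(new.astype(np.int16)),
        axis=result.axis,
        planes=result.planes,
        scheme=result.scheme,
        config=dict(result.config, closing_radius_mm=float(radius_mm)),
        warnings=result.warnings,
        timings_s=result.timings_s,
    )
    return out


def _surface(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels by 6-connectivity (array edge counts as background)."""
    structure = ndi.generate_binary_structure(3, 1)
    return mask & ~ndi.binary_erosion(mask, structure=structure)


def _fill_from_surface(
    seeded: SegmentationResult, myoset: MyocardiumSet, radius_mm: float
) -> SegmentationResult:
    """Surface-closing mode: propagate surface labels to the full shell.

    Each seeded segment is closed (dilation+erosion) within the shell; voxels
    claimed by exactly one closed segment take that label, everything still
    unlabeled takes the label of the nearest seeded voxel (Euclidean, mm).
    Seeded voxels always keep their own label.
    """
    myo = myoset.myo.data.astype(bool)
    seed = seeded.labels.data
    spacing = seeded.labels.spacing
    new = seed.copy()

    if radius_mm > 0:
        structure = _ball_structure(radius_mm, spacing)
        claims = np.zeros(seed.shape, dtype=np.int8)
        claimed_label = np.zeros(seed.shape, dtype=np.int16)
        for lab in np.unique(seed[seed > 0]):
            closed = ndi.binary_closing(seed == lab, structure=structure) & myo
            claims += closed
            claimed_label[closed] = lab
        fill = (new == 0) & myo & (claims == 1)
        new[fill] = claimed_label[fill]
        new[seed > 0] = seed[seed > 0]

    remaining = (new == 0) & myo
    if remaining.any():
        # nearest seeded voxel in physical mm
        _, idx = ndi.distance_transform_edt(
            seed == 0, sampling=spacing, return_indices=True
        )
        new[remaining] = seed[tuple(i[remaining] for i in idx)]

    return SegmentationResult(
        labels=seeded.labels.with_data(new.astype(np.int16)),
        axis=seeded.axis,
        planes=seeded.planes,
        scheme=seeded.scheme,
        config=seeded.config,
        warnings=seeded.warnings,
        timings_s=seeded.timings_s,
    )


# ----------------------------------------------------------------------
def run_asset(
    lv_mask: VolumeGrid,
    rv_point: np.ndarray,
    config: RunConfig | None = None,
) -> SegmentationResult:
    """End-to-end pipeline: long axis -> shell -> planes -> sectors -> closing.

    ``mode="voxel"`` labels every shell voxel directly.
    ``mode="surface_closing"`` reproduces the surface variant: labels are
    assigned only on the endocardial+epicardial boundary voxels of the shell
    and morphological closing (plus nearest-seed fill) produces the final
    contours.
    """
    cfg = config or RunConfig()
    cfg.validate()
    timings: dict[str, float] = {}

    def _stage(name: str, fn, *args, **kw):
        tic = time.perf_counter()
        out = fn(*args, **kw)
        timings[name] = time.perf_counter() - tic
        return out

    axis = _stage("compute_plax", compute_plax, lv_mask)
    axis = _stage(
        "orient", orient_base_to_apex, axis, lv_mask, force_sign=cfg.force_orientation
    )
    myoset = _stage("make_myocardium", make_myocardium, lv_mask, cfg.thickness_mm)
    if cfg.basal_cut_t is not None:
        myoset = _stage("remove_basal_cap", remove_basal_cap, myoset, axis, cfg.basal_cut_t)
    planes = _stage("region_planes", region_planes, myoset, axis, cfg.apex_rule_tuple())

    restrict = None
    if cfg.mode == "surface_closing":
        restrict = _surface(myoset.myo.data.astype(bool))
    result = _stage(
        "assign_segments",
        assign_segments,
        myoset,
        axis,
        np.asarray(rv_point, float),
        planes,
        flip_rotation=cfg.flip_rotation,
        restrict_to=restrict,
    )
    if cfg.mode == "surface_closing":
        result = _stage("surface_fill", _fill_from_surface, result, myoset, cfg.closing_radius_mm)
    elif cfg.closing_radius_mm > 0:
        result = _stage(
            "close_segments",
            close_segments,
            result,
            cfg.closing_radius_mm,
            myoset.myo.data.astype(bool),
        )

    result.config = cfg.to_dict()
    result.timings_s = timings
    for w in myoset.warnings:
        result.warnings.add(w)
    missing = sorted(set(range(1, 18)) - set(result.present_labels()))
    for m in missing:
        msg = f"segment {m} ({SEGMENT_NAMES[m]}) has zero voxels"
        if msg not in result.warnings.messages:
            result.warnings.add(msg)
    return result
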