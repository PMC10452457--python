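"""Long-axis estimation and line/angle primitives.

The parasternal long axis (PLAX) is estimated as the first principal component
of the physical-mm coordinates of all LV mask voxel centers.  Eigenvector sign
is resolved separately (:func:`orient_base_to_apex`): the apex is taken to be
the extent end with the smaller orthogonal cross-section.

Axis comparison mirrors the validation used for physician-vs-automatic axes:
an undirected angle in [0, 90] degrees and a symmetric segment-to-line mean
distance sampled at a configurable step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import (
    AmbiguousAxisError,
    EmptyMaskError,
    OrientationAmbiguousError,
    UndefinedAzimuthError,
    ValidationError,
    VolumeGrid,
)

_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class Axis:
    """An oriented 3D line segment in physical mm.

    ``anchor`` is a point on the line, ``direction`` a unit vector oriented
    base -> apex, and ``[t_min, t_max]`` the axial extent of the supporting
    mask projected onto the line (mm, relative to ``anchor``).
    """

    anchor: np.ndarray
    direction: np.ndarray
    t_min: float
    t_max: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "anchor", np.asarray(self.anchor, dtype=float))
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n < _UNIT_TOL:
            raise ValidationError("axis direction is the zero vector")
        if abs(n - 1.0) > 1e-6:
            d = d / n
        object.__setattr__(self, "direction", d)
        if not self.t_min < self.t_max:
            raise ValidationError(
                f"axis extent degenerate: t_min={self.t_min} >= t_max={self.t_max}"
            )

    # ------------------------------------------------------------------
    @property
    def length(self) -> float:
        return self.t_max - self.t_min

    def point_at(self, t: float | np.ndarray) -> np.ndarray:
        return self.anchor + np.multiply.outer(np.asarray(t, float), self.direction)

    def axial_coord(self, points: np.ndarray) -> np.ndarray:
        """Signed projection of points onto the axis, mm from ``anchor``."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.anchor) @ self.direction

    def radial_vector(self, points: np.ndarray) -> np.ndarray:
        """Component of (p - anchor) orthogonal to the axis, shape (N, 3)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        w = pts - self.anchor
        t = w @ self.direction
        return w - np.outer(t, self.direction)

    def flipped(self) -> "Axis":
        return Axis(self.anchor, -self.direction, -self.t_max, -self.t_min)

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "anchor": [float(x) for x in self.anchor],
            "direction": [float(x) for x in self.direction],
            "t_min": float(self.t_min),
            "t_max": float(self.t_max),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Axis":
        return cls(
            np.asarray(d["anchor"], float),
            np.asarray(d["direction"], float),
            float(d["t_min"]),
            float(d["t_max"]),
        )

    @classmethod
    def from_two_points(cls, p_base: np.ndarray, p_apex: np.ndarray) -> "Axis":
        """Axis through two points, oriented first -> second (base -> apex)."""
        p_base = np.asarray(p_base, float)
        p_apex = np.asarray(p_apex, float)
        v = p_apex - p_base
        n = np.linalg.norm(v)
        if n < 1e-9:
            raise ValidationError("the two axis points coincide")
        return cls(p_base, v / n, 0.0, float(n))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


@dataclass(frozen=True)
class AxisComparison:
    """Agreement between two axes: mean line distance (mm), angle (degrees)."""

    mean_distance_mm: float
    angle_deg: float

    def __post_init__(self) -> None:
        if self.mean_distance_mm < 0:
            raise ValidationError("mean distance must be >= 0")
        if not 0.0 <= self.angle_deg <= 90.0 + 1e-9:
            raise ValidationError("line angle must lie in [0, 90] degrees")


# ----------------------------------------------------------------------
def compute_plax(lv_mask: VolumeGrid, *, eig_rel_tol: float = 1e-6) -> Axis:
    """Estimate the long axis as the first principal component of the mask.

    PCA runs on the physical-mm coordinates of *all* mask voxel centers.  The
    direction is the eigenvector of their covariance matrix with the largest
    eigenvalue; the anchor is the centroid; ``t_min``/``t_max`` are the
    min/max projections of the mask voxels onto the direction.

    Raises
    ------
    EmptyMaskError
        if the mask has no voxels.
    AmbiguousAxisError
        if the two largest eigenvalues coincide within ``eig_rel_tol``
        (relative), i.e. there is no unique major axis.
    """
    lv_mask.require_binary()
    pts = lv_mask.mask_world_coords()
    if pts.shape[0] == 0:
        raise EmptyMaskError("cannot compute a long axis from an empty mask")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered / pts.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    if eigvals[2] <= 0:
        raise AmbiguousAxisError("mask has no spatial extent")
    if (eigvals[2] - eigvals[1]) <= eig_rel_tol * eigvals[2]:
        raise AmbiguousAxisError(
            "largest two eigenvalues are equal within tolerance; "
            f"no unique major axis (eigenvalues={eigvals})"
        )
    direction = eigvecs[:, 2]
    t = centered @ direction
    return Axis(centroid, direction, float(t.min()), float(t.max()))


def orient_base_to_apex(
    axis: Axis,
    lv_mask: VolumeGrid,
    *,
    terminal_fraction: float = 0.10,
    area_rel_tol: float = 0.01,
    force_sign: int | None = None,
) -> Axis:
    """Resolve the PCA sign ambiguity so ``direction`` points base -> apex.

    The apex is defined as the extent end whose orthogonal cross-sectional
    mask area, averaged over the terminal ``terminal_fraction`` of
    ``[t_min, t_max]``, is smaller.  ``force_sign`` (+1 keep, -1 flip)
    bypasses the rule for pathological inputs.

    Raises
    ------
    OrientationAmbiguousError
        if the two terminal areas agree within ``area_rel_tol`` (relative).
    """
    if force_sign is not None:
        if force_sign not in (+1, -1):
            raise ValidationError("force_sign must be +1 or -1")
        return axis if force_sign == +1 else axis.flipped()

    lv_mask.require_binary()
    pts = lv_mask.mask_world_coords()
    if pts.shape[0] == 0:
        raise EmptyMaskError("cannot orient an axis against an empty mask")
    t = axis.axial_coord(pts)
    slab = terminal_fraction * axis.length
    if slab <= 0:
        raise ValidationError("axis has zero length")
    vol = lv_mask.voxel_volume_mm3
    # average cross-sectional area over each terminal slab = slab volume / slab length
    area_lo = np.count_nonzero(t <= axis.t_min + slab) * vol / slab
    area_hi = np.count_nonzero(t >= axis.t_max - slab) * vol / slab
    big = max(area_lo, area_hi)
    if big <= 0 or abs(area_lo - area_hi) <= area_rel_tol * big:
        raise OrientationAmbiguousError(
            f"terminal cross-sections indistinguishable "
            f"(low end {area_lo:.1f} mm^2, high end {area_hi:.1f} mm^2); "
            "pass force_sign to override"
        )
    # apex = smaller end; direction must point toward it
    return axis if area_hi < area_lo else axis.flipped()


def angle_between_lines(d1: np.ndarray, d2: np.ndarray) -> float:
    """Undirected angle between two lines, degrees in [0, 90]."""
    d1 = np.asarray(d1, float)
    d2 = np.asarray(d2, float)
    n1, n2 = np.linalg.norm(d1), np.linalg.norm(d2)
    if n1 < _UNIT_TOL or n2 < _UNIT_TOL:
        raise ValidationError("direction vectors must be nonzero")
    c = abs(float(d1 @ d2)) / (n1 * n2)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _sample_ts(t_min: float, t_max: float, step: float) -> np.ndarray:
    n = int(np.floor((t_max - t_min) / step + 1e-9))
    return t_min + step * np.arange(n + 1)


def _dist_to_infinite_line(points: np.ndarray, line: Axis) -> np.ndarray:
    w = points - line.anchor
    t = w @ line.direction
    perp = w - np.outer(t, line.direction)
    return np.linalg.norm(perp, axis=1)


def line_mean_distance(seg_a: Axis, seg_b: Axis, step_mm: float = 1.0) -> float:
    """Symmetric mean distance between two axis segments (mm).

    Points are sampled at ``step_mm`` spacing along each segment within its
    own extent; each sample contributes its Euclidean distance to the other
    *infinite* line.  The two directed means are averaged.
    """
    if step_mm <= 0:
        raise ValidationError("step_mm must be > 0")
    for seg in (seg_a, seg_b):
        if seg.length <= 0:
            raise ValidationError("zero-length axis segment")
    pa = seg_a.point_at(_sample_ts(seg_a.t_min, seg_a.t_max, step_mm))
    pb = seg_b.point_at(_sample_ts(seg_b.t_min, seg_b.t_max, step_mm))
    mean_ab = float(_dist_to_infinite_line(pa, seg_b).mean())
    mean_ba = float(_dist_to_infinite_line(pb, seg_a).mean())
    return 0.5 * (mean_ab + mean_ba)


def azimuth(
    p: np.ndarray,
    axis: Axis,
    ref_dir: np.ndarray,
    *,
    flip_rotation: bool = False,
) -> float:
    """Azimuth of point ``p`` about ``axis``, degrees in [0, 360).

    Zero azimuth is the (axis-orthogonal) ``ref_dir``; positive rotation
    follows the right-hand rule about ``axis.direction`` unless
    ``flip_rotation`` inverts the chirality.
    """
    ref_dir = np.asarray(ref_dir, float)
    if abs(np.linalg.norm(ref_dir) - 1.0) > 1e-6:
        raise ValidationError("ref_dir must be a unit vector")
    if abs(float(ref_dir @ axis.direction)) > 1e-6:
        raise ValidationError("ref_dir must be orthogonal to the axis direction")
    v = axis.radial_vector(p)[0]
    if np.linalg.norm(v) <= 1e-6:
        raise UndefinedAzimuthError("point lies on the axis; azimuth undefined")
    e2 = np.cross(axis.direction, ref_dir)
    if flip_rotation:
        e2 = -e2
    theta = np.degrees(np.arctan2(float(v @ e2), float(v @ ref_dir)))
    return float(theta % 360.0)


def compare_axes(physician: Axis, pca: Axis, step_mm: float = 1.0) -> AxisComparison:
    """Angle and symmetric mean line distance between two axes."""
    return AxisComparison(
        mean_distance_mm=line_mean_distance(physician, pca, step_mm),
        angle_deg=angle_between_lines(physician.direction, pca.direction),
    )
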