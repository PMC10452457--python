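"""Core data carrier (:class:`VolumeGrid`) and the package exception hierarchy.

All geometric computation in this package happens in physical millimetres.
Voxel indices appear only at the I/O boundary; a :class:`VolumeGrid` couples a
voxel array to the 4x4 affine that maps voxel indices to physical mm, exactly
as stored in the source NIfTI file.  No axis is ever flipped silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class AssetError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(AssetError):
    """Input failed a precondition (non-binary mask, bad affine, ...)."""


class EmptyMaskError(ValidationError):
    """An operation received an empty binary mask."""


class AmbiguousAxisError(AssetError):
    """PCA could not identify a unique major axis (degenerate eigenvalues)."""


class OrientationAmbiguousError(AssetError):
    """Base and apex ends of the long axis cannot be told apart."""


class UndefinedAzimuthError(AssetError):
    """Azimuth requested for a point lying on the long axis."""


class GridMismatchError(ValidationError):
    """Two volumes expected on the same grid have different shape or affine."""


@dataclass
class VolumeGrid:
    """A 3D scalar/label array plus the affine mapping voxel index -> mm.

    Parameters
    ----------
    data:
        3D array; boolean for masks, small integers for label maps.
    affine:
        4x4 homogeneous matrix; column ``i`` of the 3x3 block is the physical
        step between neighbouring voxels along array axis ``i``.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError(f"expected a 3D array, got ndim={self.data.ndim}")
        if self.affine.shape != (4, 4):
            raise ValidationError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValidationError("affine is singular")

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Physical step length (mm) along each array axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    # ------------------------------------------------------------------
    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (N,3) voxel indices (may be fractional) to (N,3) mm points."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def mask_world_coords(self) -> np.ndarray:
        """Physical-mm centers of all nonzero voxels, shape (N, 3)."""
        ijk = np.argwhere(self.data)
        return self.voxel_to_world(ijk)

    # ------------------------------------------------------------------
    def same_grid(self, other: "VolumeGrid", atol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_same_grid(self, other: "VolumeGrid") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grids differ: shape {self.shape} vs {other.shape} "
                "or affines do not match"
            )

    def require_binary(self) -> None:
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValidationError(
                f"expected a binary mask with values in {{0,1}}, found {vals[:10]}"
            )

    def astype_bool(self) -> "VolumeGrid":
        return VolumeGrid(self.data.astype(bool), self.affine)

    def count(self) -> int:
        return int(np.count_nonzero(self.data))

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        """New grid sharing this affine."""
        return VolumeGrid(data, self.affine)


@dataclass
class Warnings:
    """Accumulator for non-fatal conditions attached to results."""

    messages: list[str] = field(default_factory=list)

    def add(self, msg: str) -> None:
        self.messages.append(msg)

    def __bool__(self) -> bool:
        return bool(self.messages)

    def __iter__(self):
        return iter(self.messages)
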