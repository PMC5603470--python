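"""Core in-memory image types shared by all segmentation routines.

A volume is stored as a 3-D array indexed ``data[i, j, k]`` together with an
affine geometry (voxel spacing in mm, world origin in mm, direction cosine
matrix).  The world position of voxel center ``(i, j, k)`` is::

    world = origin + direction @ (spacing * (i, j, k))

A voxel belongs to a geometric region if and only if its *center* does; this
single inclusion rule is used everywhere (ellipsoid VOIs, sphere phantoms,
contour rasterization).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["ImageGeometry", "SUVImage", "SegmentationMask", "mask_volume_cm3"]


@dataclass(frozen=True)
class ImageGeometry:
    """Affine placement of a regular 3-D grid in world space (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3:
            raise ValueError("geometry must be 3-D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive in all axes")

    @property
    def direction_matrix(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float).reshape(3, 3)

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine."""
        aff = np.eye(4)
        aff[:3, :3] = self.direction_matrix * np.asarray(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices (may be fractional) to world mm."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx * np.asarray(self.spacing) @ self.direction_matrix.T + np.asarray(
            self.origin
        )

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 3) world-mm points to fractional voxel indices."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        local = (pts - np.asarray(self.origin)) @ np.linalg.inv(self.direction_matrix).T
        return local / np.asarray(self.spacing)

    def voxel_centers_world(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``shape + (3,)``."""
        idx = np.indices(self.shape, dtype=float).reshape(3, -1).T
        return self.index_to_world(idx).reshape(*self.shape, 3)


@dataclass
class SUVImage:
    """3-D scalar volume in body-weight SUV units."""

    data: np.ndarray
    geometry: ImageGeometry
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("SUVImage requires a 3-D array")
        if tuple(self.data.shape) != tuple(self.geometry.shape):
            raise ValueError(
                f"array shape {self.data.shape} does not match geometry "
                f"{self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("SUV values must be finite")
        if np.any(self.data < 0):
            raise ValueError("SUV values must be non-negative")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.geometry.spacing

    @property
    def voxel_volume_cm3(self) -> float:
        return self.geometry.voxel_volume_cm3

    @classmethod
    def from_array(
        cls,
        data: np.ndarray,
        spacing: tuple[float, float, float],
        origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
        direction: np.ndarray | None = None,
        provenance: dict[str, Any] | None = None,
    ) -> "SUVImage":
        data = np.asarray(data, dtype=float)
        if direction is None:
            dir_flat = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)
        else:
            dir_flat = tuple(np.asarray(direction, dtype=float).reshape(9))
        geom = ImageGeometry(
            shape=tuple(data.shape),
            spacing=tuple(float(s) for s in spacing),
            origin=tuple(float(o) for o in origin),
            direction=dir_flat,
        )
        return cls(data=data, geometry=geom, provenance=provenance or {})


@dataclass
class SegmentationMask:
    """Binary voxel mask aligned to a parent :class:`SUVImage` grid."""

    data: np.ndarray
    geometry: ImageGeometry
    method: str = "unspecified"
    parameters: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("SegmentationMask requires a 3-D array")
        if tuple(self.data.shape) != tuple(self.geometry.shape):
            raise ValueError("mask shape does not match geometry")

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_cm3(self) -> float:
        return self.voxel_count * self.geometry.voxel_volume_cm3


def mask_volume_cm3(mask: SegmentationMask) -> float:
    """Mask volume in cm^3: voxel count times voxel volume.

    An empty mask yields 0 cm^3 (a warning is the caller's concern; this is
    pure arithmetic).
    """
    return mask.volume_cm3
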