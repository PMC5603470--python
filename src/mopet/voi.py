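"""Ellipsoidal volume-of-interest definition and voxelization.

VOIs are specified in world millimetres so the same VOI applies across
resampled grids.  A voxel is inside the VOI iff its center satisfies the
ellipsoid inequality (the codebase-wide center-inclusion rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .image import ImageGeometry, SegmentationMask

__all__ = ["EllipsoidVOI"]


@dataclass(frozen=True)
class EllipsoidVOI:
    """Ellipsoid in world mm: center, semi-axes, optional ZYX Euler rotation.

    ``euler_zyx_deg`` rotates the ellipsoid axes relative to the world axes
    (intrinsic Z-Y-X order, degrees); identity by default.
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    euler_zyx_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.center) != 3 or len(self.semi_axes) != 3:
            raise ValueError("center and semi_axes must be 3-vectors")
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be positive")

    @property
    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("ZYX", self.euler_zyx_deg, degrees=True).as_matrix()

    @property
    def volume_cm3(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c / 1000.0

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership for (N, 3) world-mm points (boundary inclusive)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        local = (pts - np.asarray(self.center)) @ self.rotation_matrix
        q = np.sum((local / np.asarray(self.semi_axes)) ** 2, axis=1)
        return q <= 1.0

    def to_mask(self, geometry: ImageGeometry) -> SegmentationMask:
        """Voxelize on a grid; raises if the VOI misses the grid entirely."""
        centers = geometry.voxel_centers_world().reshape(-1, 3)
        inside = self.contains(centers).reshape(geometry.shape)
        if not inside.any():
            raise ValueError(
                "VOI does not intersect the image grid (no voxel center inside)"
            )
        return SegmentationMask(
            data=inside,
            geometry=geometry,
            method="voi-ellipsoid",
            parameters={
                "center": list(self.center),
                "semi_axes": list(self.semi_axes),
                "euler_zyx_deg": list(self.euler_zyx_deg),
            },
        )

    def to_dict(self) -> dict:
        return {
            "center": list(self.center),
            "semi_axes": list(self.semi_axes),
            "euler_zyx_deg": list(self.euler_zyx_deg),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EllipsoidVOI":
        return cls(
            center=tuple(float(x) for x in d["center"]),
            semi_axes=tuple(float(x) for x in d["semi_axes"]),
            euler_zyx_deg=tuple(float(x) for x in d.get("euler_zyx_deg", (0, 0, 0))),
        )


def voi_to_mask(voi: EllipsoidVOI, geometry: ImageGeometry) -> SegmentationMask:
    """Functional alias for :meth:`EllipsoidVOI.to_mask`."""
    return voi.to_mask(geometry)
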