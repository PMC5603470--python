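"""Planar contour sets and rasterization onto image grids.

Structures are lists of closed planar polygons in world mm.  Rasterization
follows the codebase inclusion rule: a voxel is inside a structure iff its
center is inside one of the structure's polygons on that slice, using the
even-odd (ray-crossing) fill rule.  The even-odd test is the contract here,
so it is implemented directly (vectorized) rather than delegated to a
renderer with a different fill rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from ..image import ImageGeometry, SegmentationMask

__all__ = [
    "StructureContours",
    "ContourSet",
    "points_in_polygon",
    "rasterize_contours",
    "mask_to_contours",
]


@dataclass(frozen=True)
class StructureContours:
    """One named structure: closed planar polygons in world mm."""

    name: str
    polygons: tuple[np.ndarray, ...]  # each (N, 3), N >= 3, planar, closed

    def __post_init__(self) -> None:
        polys = tuple(np.asarray(p, dtype=float) for p in self.polygons)
        object.__setattr__(self, "polygons", polys)
        for p in polys:
            if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 3:
                raise ValueError("each polygon must be (N>=3, 3) world-mm vertices")


@dataclass
class ContourSet:
    """Named structures read from RTSS or built programmatically."""

    structures: dict[str, StructureContours] = field(default_factory=dict)

    def add(self, name: str, polygons) -> None:
        self.structures[name] = StructureContours(name=name, polygons=tuple(polygons))

    def __getitem__(self, name: str) -> StructureContours:
        return self.structures[name]

    def names(self) -> list[str]:
        return list(self.structures)


def points_in_polygon(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Even-odd (crossing-number) point-in-polygon test, vectorized.

    ``points`` is (M, 2), ``polygon`` (N, 2); the polygon closes implicitly.
    Points exactly on a horizontal edge follow the half-open edge convention
    (standard crossing test), which keeps adjacent polygons non-overlapping.
    """
    pts = np.asarray(points, dtype=float)
    poly = np.asarray(polygon, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    x0, y0 = poly[:, 0], poly[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    inside = np.zeros(len(pts), dtype=bool)
    for xa, ya, xb, yb in zip(x0, y0, x1, y1):
        crosses = (ya > y) != (yb > y)
        if not crosses.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = xa + (y - ya) / (yb - ya) * (xb - xa)
        inside ^= crosses & (x < xint)
    return inside


def rasterize_contours(
    contours: StructureContours | ContourSet,
    geometry: ImageGeometry,
    structure: str | None = None,
    slice_axis: int = 2,
    slice_tolerance: float | None = None,
) -> SegmentationMask:
    """Rasterize a structure's planar polygons to a 3-D mask.

    Each polygon is assigned to the grid slice whose plane coordinate is
    nearest (within half a slice spacing by default); in-plane membership is
    voxel-center-in-polygon under the even-odd rule.  Polygons on the same
    slice combine by exclusive-or, so RTSS-style holes are honored.

    Raises
    ------
    ValueError
        If a polygon's plane does not match any grid slice within tolerance.
    """
    if isinstance(contours, ContourSet):
        if structure is None:
            if len(contours.structures) != 1:
                raise ValueError("multiple structures present; name one")
            structure = next(iter(contours.structures))
        contours = contours[structure]

    axes_in_plane = [a for a in range(3) if a != slice_axis]
    spacing = geometry.spacing
    if slice_tolerance is None:
        slice_tolerance = 0.5 * spacing[slice_axis]

    mask = np.zeros(geometry.shape, dtype=bool)
    # in-plane voxel-center coordinates, computed once per needed slice
    plane_shape = tuple(geometry.shape[a] for a in axes_in_plane)
    plane_centers: dict[int, np.ndarray] = {}

    for poly in contours.polygons:
        idx = geometry.world_to_index(poly)
        k_float = idx[:, slice_axis]
        k = int(np.round(np.mean(k_float)))
        if not (0 <= k < geometry.shape[slice_axis]):
            raise ValueError(
                f"contour plane (index {np.mean(k_float):.3f}) outside grid"
            )
        off_mm = abs(float(np.mean(k_float)) - k) * spacing[slice_axis]
        if off_mm > slice_tolerance:
            raise ValueError(
                f"contour plane {off_mm:.3f} mm from nearest slice "
                f"(tolerance {slice_tolerance:.3f} mm)"
            )
        if k not in plane_centers:
            grids = np.meshgrid(
                *(np.arange(geometry.shape[a], dtype=float) for a in axes_in_plane),
                indexing="ij",
            )
            full = np.zeros(plane_shape + (3,))
            full[..., axes_in_plane[0]] = grids[0]
            full[..., axes_in_plane[1]] = grids[1]
            full[..., slice_axis] = k
            plane_centers[k] = full.reshape(-1, 3)
        pts2 = plane_centers[k][:, axes_in_plane]
        poly2 = idx[:, axes_in_plane]
        inside = points_in_polygon(pts2, poly2).reshape(plane_shape)
        sl: list = [slice(None)] * 3
        sl[slice_axis] = k
        mask[tuple(sl)] ^= inside

    return SegmentationMask(
        data=mask,
        geometry=geometry,
        method="contour-raster",
        parameters={"structure": contours.name, "slice_axis": slice_axis},
    )


def mask_to_contours(
    mask: SegmentationMask,
    name: str = "mask",
    slice_axis: int = 2,
) -> ContourSet:
    """Trace per-slice iso-contours (marching squares at 0.5) of a mask.

    Contours are returned in world mm; rasterizing them back reproduces the
    original mask for reasonably shaped (e.g. convex) structures.
    """
    geometry = mask.geometry
    axes_in_plane = [a for a in range(3) if a != slice_axis]
    polys: list[np.ndarray] = []
    for k in range(geometry.shape[slice_axis]):
        sl: list = [slice(None)] * 3
        sl[slice_axis] = k
        plane = mask.data[tuple(sl)].astype(float)
        if not plane.any():
            continue
        padded = np.pad(plane, 1, mode="constant")
        for c in measure.find_contours(padded, 0.5):
            c = c - 1.0  # undo padding offset
            idx3 = np.zeros((len(c), 3))
            idx3[:, axes_in_plane[0]] = c[:, 0]
            idx3[:, axes_in_plane[1]] = c[:, 1]
            idx3[:, slice_axis] = k
            polys.append(geometry.index_to_world(idx3))
    cs = ContourSet()
    cs.add(name, polys)
    return cs
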