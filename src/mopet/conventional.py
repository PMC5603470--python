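"""Conventional PET segmentation comparators.

Absolute-SUV and percent-of-SUVmax thresholding inside an ellipsoidal VOI
(inclusive ``>=`` at the cut, no connected-component filtering by default),
plus a generic gradient-shell method labeled ``gradient (generic)`` — a
stand-in for proprietary gradient segmentation tools, not a replication of
any of them.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .image import SegmentationMask, SUVImage
from .voi import EllipsoidVOI

__all__ = [
    "segment_absolute_suv",
    "segment_percent_suvmax",
    "segment_gradient",
    "EmptyMaskWarning",
]


class EmptyMaskWarning(UserWarning):
    """Emitted when a thresholding operation selects no voxels."""


def _in_voi(image: SUVImage, voi: EllipsoidVOI) -> np.ndarray:
    return voi.to_mask(image.geometry).data


def _component_filter(mask: np.ndarray, image: SUVImage, inside: np.ndarray) -> np.ndarray:
    if not mask.any():
        return mask
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    values = np.where(inside, image.data, -np.inf)
    max_idx = np.unravel_index(np.argmax(values), values.shape)
    if mask[max_idx]:
        return labels == labels[max_idx]
    return mask


def segment_absolute_suv(
    image: SUVImage,
    voi: EllipsoidVOI,
    threshold: float,
    connected_only: bool = False,
) -> SegmentationMask:
    """In-VOI voxels with SUV >= ``threshold`` (an absolute SUV cut).

    Disconnected voxels are included unless ``connected_only`` is set, in
    which case only the component containing the SUV-max voxel is kept.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    inside = _in_voi(image, voi)
    sel = inside & (image.data >= threshold)
    if connected_only:
        sel = _component_filter(sel, image, inside)
    if not sel.any():
        warnings.warn(
            f"absolute-SUV threshold {threshold} selects no voxels",
            EmptyMaskWarning,
            stacklevel=2,
        )
    return SegmentationMask(
        data=sel,
        geometry=image.geometry,
        method=f"suv-{threshold:g}",
        parameters={"threshold": float(threshold), "connected_only": connected_only},
    )


def segment_percent_suvmax(
    image: SUVImage,
    voi: EllipsoidVOI,
    fraction: float,
    connected_only: bool = False,
) -> SegmentationMask:
    """In-VOI voxels with SUV >= ``fraction`` x in-VOI SUV-max."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    inside = _in_voi(image, voi)
    suv_max = float(image.data[inside].max())
    cut = fraction * suv_max
    sel = inside & (image.data >= cut)
    if connected_only:
        sel = _component_filter(sel, image, inside)
    if not sel.any():  # pragma: no cover - cut <= suv_max guarantees >= 1 voxel
        warnings.warn("percent-SUVmax selects no voxels", EmptyMaskWarning, stacklevel=2)
    return SegmentationMask(
        data=sel,
        geometry=image.geometry,
        method=f"pct-{100 * fraction:g}",
        parameters={"fraction": float(fraction), "suv_max": suv_max, "threshold": cut},
    )


def _fibonacci_directions(n: int) -> np.ndarray:
    """n deterministic, near-uniform unit vectors on the sphere."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def segment_gradient(
    image: SUVImage,
    voi: EllipsoidVOI,
    smoothing_fwhm: float = 0.0,
    n_directions: int = 512,
    step_mm: float | None = None,
) -> SegmentationMask:
    """Gradient-shell segmentation from the in-VOI SUV-max voxel.

    The in-VOI subvolume is Gaussian-smoothed (``smoothing_fwhm`` mm, 0 to
    disable), the gradient magnitude is computed with physical spacing, and
    for each of ``n_directions`` rays from the SUV-max voxel the boundary is
    placed at the radius of maximal gradient magnitude.  A voxel is included
    if its radius along the nearest ray direction is within that boundary.
    Deterministic for fixed inputs.

    This is labeled ``gradient (generic)``: an approximation of gradient-based
    commercial tools, not a replication.
    """
    if smoothing_fwhm < 0:
        raise ValueError("smoothing_fwhm must be >= 0")
    inside = _in_voi(image, voi)
    values = image.data[inside]
    if float(values.max()) == float(values.min()):
        raise ValueError("degenerate VOI contents: no interior maximum (flat region)")

    spacing = np.asarray(image.spacing)
    work = image.data.astype(float)
    if smoothing_fwhm > 0:
        sigma_vox = smoothing_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / spacing
        work = ndimage.gaussian_filter(work, sigma=sigma_vox, mode="nearest")

    grads = np.gradient(work, *spacing)
    gmag = np.sqrt(sum(g * g for g in grads))

    flat_max = np.flatnonzero(inside.ravel())[np.argmax(values)]
    seed_idx = np.asarray(np.unravel_index(flat_max, image.data.shape), dtype=float)
    seed_world = image.geometry.index_to_world(seed_idx)[0]

    max_radius = float(np.max(voi.semi_axes)) * 2.0
    if step_mm is None:
        step_mm = 0.5 * float(spacing.min())
    n_steps = max(int(np.ceil(max_radius / step_mm)), 4)
    radii = (np.arange(n_steps) + 1) * step_mm
    dirs = _fibonacci_directions(n_directions)

    # sample gradient magnitude along all rays with trilinear interpolation
    pts = seed_world[None, None, :] + radii[None, :, None] * dirs[:, None, :]
    idx = image.geometry.world_to_index(pts.reshape(-1, 3)).T
    samples = ndimage.map_coordinates(
        gmag, idx, order=1, mode="constant", cval=0.0
    ).reshape(n_directions, n_steps)

    # mask out samples beyond the VOI surface along each ray
    in_voi_samples = voi.contains(pts.reshape(-1, 3)).reshape(n_directions, n_steps)
    samples = np.where(in_voi_samples, samples, -np.inf)
    boundary_r = radii[np.argmax(samples, axis=1)]

    voi_idx = np.argwhere(inside)
    centers = image.geometry.index_to_world(voi_idx.astype(float))
    rel = centers - seed_world
    dist = np.linalg.norm(rel, axis=1)
    safe = np.where(dist > 0, dist, 1.0)
    unit = rel / safe[:, None]
    nearest = np.argmax(unit @ dirs.T, axis=1)
    keep = dist <= boundary_r[nearest] + 0.5 * float(spacing.max())
    sel = np.zeros(image.data.shape, dtype=bool)
    sel[tuple(voi_idx[keep].T)] = True
    sel = _component_filter(sel, image, inside)
    return SegmentationMask(
        data=sel,
        geometry=image.geometry,
        method="gradient (generic)",
        parameters={
            "smoothing_fwhm": float(smoothing_fwhm),
            "n_directions": int(n_directions),
            "step_mm": float(step_mm),
        },
    )
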