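"""NIfTI-1 read/write for SUV volumes and binary masks (via nibabel).

The voxel->world affine is stored verbatim in the NIfTI header, so array,
spacing, origin and direction survive a round trip losslessly (geometry to
float precision).  Coordinate-frame semantics (RAS vs LPS) are the caller's
responsibility; this layer preserves whatever affine it is given.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from ..image import ImageGeometry, SegmentationMask, SUVImage

__all__ = ["read_nifti", "write_nifti", "read_mask_nifti"]


def _geometry_from_affine(shape: tuple[int, int, int], affine: np.ndarray) -> ImageGeometry:
    linear = affine[:3, :3]
    spacing = np.linalg.norm(linear, axis=0)
    direction = linear / spacing
    return ImageGeometry(
        shape=tuple(int(s) for s in shape),
        spacing=tuple(float(s) for s in spacing),
        origin=tuple(float(o) for o in affine[:3, 3]),
        direction=tuple(float(d) for d in direction.reshape(9)),
    )


def read_nifti(path: str | Path) -> SUVImage:
    """Load a 3-D NIfTI volume as an :class:`SUVImage`."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {data.shape}")
    geom = _geometry_from_affine(data.shape, np.asarray(img.affine, dtype=float))
    sidecar = Path(str(path)).with_suffix("").with_suffix(".json")
    provenance = {"source": str(path), "format": "nifti"}
    if sidecar.exists():
        provenance.update(json.loads(sidecar.read_text()))
    return SUVImage(data=data, geometry=geom, provenance=provenance)


def read_mask_nifti(path: str | Path) -> SegmentationMask:
    """Load a NIfTI volume as a binary mask (non-zero -> True)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D mask, got shape {data.shape}")
    geom = _geometry_from_affine(data.shape, np.asarray(img.affine, dtype=float))
    return SegmentationMask(data=data != 0, geometry=geom, method="loaded")


def write_nifti(
    obj: SUVImage | SegmentationMask,
    path: str | Path,
    sidecar: bool = False,
) -> None:
    """Write a volume (float64) or mask (uint8) to NIfTI-1.

    With ``sidecar=True`` a JSON file next to the image records provenance
    (for images) or method/parameters (for masks).
    """
    if isinstance(obj, SegmentationMask):
        data = obj.data.astype(np.uint8)
        meta = {"method": obj.method, "parameters": obj.parameters}
    else:
        data = obj.data.astype(np.float64)
        meta = dict(obj.provenance)
    img = nib.Nifti1Image(data, affine=obj.geometry.affine)
    nib.save(img, str(path))
    if sidecar:
        side = Path(str(path)).with_suffix("").with_suffix(".json")
        side.write_text(json.dumps(meta, indent=2, default=str))
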