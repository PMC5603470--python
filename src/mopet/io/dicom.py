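"""PET DICOM series loading with body-weight SUV conversion; RTSS reading.

The SUV arithmetic (decay correction, body-weight normalization) lives in
:class:`PetSuvHeader` / :func:`suv_scale_factor` and is pure and fully
testable.  Reading actual DICOM bytes requires the optional ``pydicom``
dependency; a clear ImportError is raised if it is missing.

Body-weight SUV of a voxel with activity concentration ``c`` (Bq/mL)::

    SUV_bw = c * weight_g / dose_at_scan_Bq

where the injected dose is decay-corrected from injection time to the
series' decay-correction reference time using the isotope half-life
(F-18 default: 6586.2 s).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..image import ImageGeometry, SUVImage
from .contours import ContourSet

__all__ = ["PetSuvHeader", "suv_scale_factor", "load_pet_suv", "read_rtss"]

F18_HALF_LIFE_S = 6586.2


def _require_pydicom():
    try:
        import pydicom  # noqa: PLC0415
    except ImportError as exc:  # pragma: no cover - exercised only without extra
        raise ImportError(
            "DICOM support requires the optional 'pydicom' dependency "
            "(pip install mopet[dicom])"
        ) from exc
    return pydicom


@dataclass(frozen=True)
class PetSuvHeader:
    """The header fields needed for body-weight SUV conversion."""

    patient_weight_kg: float
    injected_dose_bq: float
    injection_time_s: float  # seconds since midnight
    reference_time_s: float  # decay-correction reference, seconds since midnight
    half_life_s: float = F18_HALF_LIFE_S
    decay_corrected: bool = True  # pixel data already corrected to reference time

    def __post_init__(self) -> None:
        missing = [
            name
            for name, v in (
                ("patient weight", self.patient_weight_kg),
                ("injected dose", self.injected_dose_bq),
                ("half-life", self.half_life_s),
            )
            if not (v and v > 0)
        ]
        if missing:
            raise ValueError(f"cannot compute SUV: missing/invalid {', '.join(missing)}")

    @property
    def elapsed_s(self) -> float:
        dt = self.reference_time_s - self.injection_time_s
        if dt < 0:
            dt += 24 * 3600.0  # scan past midnight
        return dt

    @property
    def decayed_dose_bq(self) -> float:
        return self.injected_dose_bq * 2.0 ** (-self.elapsed_s / self.half_life_s)


def suv_scale_factor(header: PetSuvHeader) -> float:
    """Multiplier turning activity concentration (Bq/mL) into SUV_bw."""
    return header.patient_weight_kg * 1000.0 / header.decayed_dose_bq


def _parse_dicom_time(value: str) -> float:
    value = str(value)
    h, m = int(value[0:2]), int(value[2:4])
    s = float(value[4:]) if len(value) > 4 else 0.0
    return h * 3600.0 + m * 60.0 + s


def _header_from_dataset(ds) -> PetSuvHeader:
    missing: list[str] = []
    weight = getattr(ds, "PatientWeight", None)
    if weight is None:
        missing.append("PatientWeight")
    radio = getattr(ds, "RadiopharmaceuticalInformationSequence", None)
    dose = start = half_life = None
    if radio is None or len(radio) == 0:
        missing += ["RadionuclideTotalDose", "RadiopharmaceuticalStartTime"]
    else:
        item = radio[0]
        dose = getattr(item, "RadionuclideTotalDose", None)
        if dose is None:
            missing.append("RadionuclideTotalDose")
        start = getattr(item, "RadiopharmaceuticalStartTime", None)
        if start is None:
            missing.append("RadiopharmaceuticalStartTime")
        half_life = getattr(item, "RadionuclideHalfLife", None)
    ref_time = getattr(ds, "SeriesTime", None) or getattr(ds, "AcquisitionTime", None)
    if ref_time is None:
        missing.append("SeriesTime/AcquisitionTime")
    if missing:
        raise ValueError(f"cannot compute SUV: missing tags {', '.join(missing)}")
    return PetSuvHeader(
        patient_weight_kg=float(weight),
        injected_dose_bq=float(dose),
        injection_time_s=_parse_dicom_time(start),
        reference_time_s=_parse_dicom_time(ref_time),
        half_life_s=float(half_life) if half_life else F18_HALF_LIFE_S,
        decay_corrected=str(getattr(ds, "DecayCorrection", "START")).upper() != "NONE",
    )


def load_pet_suv(dicom_dir: str | Path) -> SUVImage:
    """Read a single PET DICOM series and convert voxels to body-weight SUV.

    Requires pixel units BQML (activity concentration); slices are sorted
    along the slice normal from ImagePositionPatient.  World coordinates
    follow the DICOM patient (LPS) convention.
    """
    pydicom = _require_pydicom()
    paths = sorted(p for p in Path(dicom_dir).iterdir() if p.is_file())
    datasets = []
    for p in paths:
        try:
            datasets.append(pydicom.dcmread(str(p)))
        except Exception:  # not a DICOM file
            continue
    if not datasets:
        raise ValueError(f"no DICOM files found in {dicom_dir}")
    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) != 1:
        raise ValueError(f"mixed series in {dicom_dir}: {sorted(uids)}")
    ds0 = datasets[0]
    units = str(getattr(ds0, "Units", "")).upper()
    if units and units != "BQML":
        raise ValueError(f"unsupported pixel units {units!r}; expected BQML")

    iop = np.asarray([float(v) for v in ds0.ImageOrientationPatient])
    row_dir, col_dir = iop[:3], iop[3:]
    normal = np.cross(row_dir, col_dir)
    datasets.sort(
        key=lambda d: float(
            np.dot(normal, [float(v) for v in d.ImagePositionPatient])
        )
    )
    positions = np.array(
        [[float(v) for v in d.ImagePositionPatient] for d in datasets]
    )
    if len(datasets) > 1:
        gaps = np.diff(positions @ normal)
        slice_spacing = float(np.mean(gaps))
        if np.any(np.abs(gaps - slice_spacing) > 0.01 * abs(slice_spacing)):
            raise ValueError("non-uniform slice spacing in series")
    else:
        slice_spacing = float(getattr(ds0, "SliceThickness", 1.0))

    header = _header_from_dataset(ds0)
    factor = suv_scale_factor(header)

    slices = []
    for d in datasets:
        arr = d.pixel_array.astype(float)
        slope = float(getattr(d, "RescaleSlope", 1.0))
        intercept = float(getattr(d, "RescaleIntercept", 0.0))
        slices.append((arr * slope + intercept) * factor)
    # DICOM pixel_array is (row, col); build (col=x, row=y, slice=z) volume
    volume = np.stack(slices, axis=-1).transpose(1, 0, 2)

    row_spacing, col_spacing = (float(v) for v in ds0.PixelSpacing)
    direction = np.column_stack([row_dir, col_dir, normal])
    geom = ImageGeometry(
        shape=tuple(volume.shape),
        spacing=(col_spacing, row_spacing, abs(slice_spacing)),
        origin=tuple(positions[0]),
        direction=tuple(direction.reshape(9)),
    )
    provenance = {
        "source": str(dicom_dir),
        "format": "dicom-pet",
        "suv_type": "body-weight",
        "patient_weight_kg": header.patient_weight_kg,
        "injected_dose_bq": header.injected_dose_bq,
        "elapsed_s": header.elapsed_s,
        "half_life_s": header.half_life_s,
        "suv_scale_factor": factor,
    }
    return SUVImage(data=np.clip(volume, 0.0, None), geometry=geom, provenance=provenance)


def read_rtss(path: str | Path, structures: list[str] | None = None) -> ContourSet:
    """Read named structures from a DICOM RT Structure Set into a ContourSet."""
    pydicom = _require_pydicom()
    ds = pydicom.dcmread(str(path))
    name_by_number = {
        int(roi.ROINumber): str(roi.ROIName) for roi in ds.StructureSetROISequence
    }
    out = ContourSet()
    for roi_contour in ds.ROIContourSequence:
        number = int(roi_contour.ReferencedROINumber)
        name = name_by_number.get(number, f"ROI-{number}")
        if structures is not None and name not in structures:
            continue
        polys = []
        for contour in getattr(roi_contour, "ContourSequence", []):
            pts = np.asarray([float(v) for v in contour.ContourData]).reshape(-1, 3)
            if len(pts) >= 3:
                polys.append(pts)
        if polys:
            out.add(name, polys)
    if structures is not None:
        missing = set(structures) - set(out.names())
        if missing:
            raise ValueError(f"structures not found in RTSS: {sorted(missing)}")
    return out
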