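"""NEMA-IQ-style synthetic phantoms with known ground truth.

A phantom is a piecewise-constant SUV volume (uniform background plus hot
spheres at fixed lesion-to-background ratios), optionally convolved with an
isotropic Gaussian PSF and degraded with intensity-proportional Gaussian
noise.  Ground-truth masks always come from the unblurred geometry
(center-in-sphere rule), so they are independent of PSF and noise settings.

Default sphere diameters follow the NEMA image-quality phantom set
{10, 13, 17, 22, 28, 37} mm; default lesion-to-background ratios {2, 4, 8}.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .conventional import segment_absolute_suv, segment_gradient, segment_percent_suvmax
from .image import ImageGeometry, SegmentationMask, SUVImage
from .otsu import segment_mo_pet
from .voi import EllipsoidVOI

__all__ = [
    "NEMA_SPHERE_DIAMETERS_MM",
    "DEFAULT_LBRS",
    "SphereSpec",
    "PhantomSpec",
    "generate_phantom",
    "default_method_registry",
    "run_recovery_experiment",
    "summarize_recovery",
]

NEMA_SPHERE_DIAMETERS_MM = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
DEFAULT_LBRS = (2.0, 4.0, 8.0)


@dataclass(frozen=True)
class SphereSpec:
    """One hot sphere: center (world mm), diameter (mm), lesion/background ratio."""

    center: tuple[float, float, float]
    diameter_mm: float
    lbr: float

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("sphere diameter must be positive")
        if self.lbr <= 1:
            raise ValueError("lesion-to-background ratio must exceed 1")

    @property
    def radius_mm(self) -> float:
        return 0.5 * self.diameter_mm


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom description; fixed seed implies byte-identical output."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background_suv: float = 1.0
    spheres: tuple[SphereSpec, ...] = ()
    psf_fwhm_mm: float = 6.0
    noise_coefficient: float = 0.10  # sigma = coefficient * local intensity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_suv <= 0:
            raise ValueError("background SUV must be positive")
        if self.psf_fwhm_mm < 0 or self.noise_coefficient < 0:
            raise ValueError("psf_fwhm_mm and noise_coefficient must be >= 0")
        spheres = tuple(self.spheres)
        object.__setattr__(self, "spheres", spheres)
        for i, a in enumerate(spheres):
            for b in spheres[i + 1 :]:
                gap = np.linalg.norm(np.subtract(a.center, b.center))
                if gap < a.radius_mm + b.radius_mm:
                    raise ValueError(
                        f"overlapping spheres at {a.center} and {b.center}"
                    )

    @property
    def geometry(self) -> ImageGeometry:
        return ImageGeometry(shape=tuple(self.shape), spacing=tuple(self.spacing))

    def to_dict(self) -> dict:
        return asdict(self)


def _sphere_mask(geometry: ImageGeometry, sphere: SphereSpec) -> np.ndarray:
    centers = geometry.voxel_centers_world().reshape(-1, 3)
    d2 = np.sum((centers - np.asarray(sphere.center)) ** 2, axis=1)
    return (d2 <= sphere.radius_mm**2).reshape(geometry.shape)


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[SUVImage, list[SegmentationMask]]:
    """Simulate the phantom; returns the image and per-sphere truth masks."""
    geom = spec.geometry
    ideal = np.full(spec.shape, spec.background_suv, dtype=float)
    truths: list[SegmentationMask] = []
    for i, sphere in enumerate(spec.spheres):
        inside = _sphere_mask(geom, sphere)
        ideal[inside] = spec.background_suv * sphere.lbr
        truths.append(
            SegmentationMask(
                data=inside,
                geometry=geom,
                method="ground-truth",
                parameters={"sphere_index": i, **asdict(sphere)},
            )
        )

    blurred = ideal
    if spec.psf_fwhm_mm > 0:
        sigma_vox = (
            spec.psf_fwhm_mm
            / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            / np.asarray(spec.spacing)
        )
        blurred = ndimage.gaussian_filter(ideal, sigma=sigma_vox, mode="nearest")

    noisy = blurred
    if spec.noise_coefficient > 0:
        rng = np.random.default_rng(spec.seed)
        noisy = blurred + rng.normal(0.0, spec.noise_coefficient * blurred)
        noisy = np.clip(noisy, 0.0, None)

    image = SUVImage(
        data=noisy,
        geometry=geom,
        provenance={"format": "synthetic-phantom", **spec.to_dict()},
    )
    return image, truths


MethodFn = Callable[[SUVImage, EllipsoidVOI], SegmentationMask]


def default_method_registry(k: int = 3, n_bins: int = 128) -> dict[str, MethodFn]:
    """The comparison set: MO-PET, absolute-SUV cuts, percent cuts, gradient."""

    def mo_pet(img: SUVImage, voi: EllipsoidVOI) -> SegmentationMask:
        mask, _ = segment_mo_pet(img, voi, k=k, n_bins=n_bins)
        return mask

    registry: dict[str, MethodFn] = {"mo-pet": mo_pet}
    for thr in (2.0, 2.5, 3.0):
        registry[f"suv-{thr:.1f}"] = (
            lambda img, voi, thr=thr: segment_absolute_suv(img, voi, thr)
        )
    for pct in (30, 40, 50, 60):
        registry[f"pct-{pct}"] = (
            lambda img, voi, pct=pct: segment_percent_suvmax(img, voi, pct / 100.0)
        )
    registry["gradient (generic)"] = (
        lambda img, voi: segment_gradient(img, voi, smoothing_fwhm=0.0)
    )
    return registry


def run_recovery_experiment(
    diameters_mm: Sequence[float] = (17.0, 22.0, 28.0),
    lbrs: Sequence[float] = (4.0, 8.0),
    seeds: Sequence[int] = tuple(range(20)),
    methods: dict[str, MethodFn] | None = None,
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
    shape: tuple[int, int, int] = (64, 64, 64),
    background_suv: float = 1.0,
    psf_fwhm_mm: float = 6.0,
    noise_coefficient: float = 0.10,
    voi_margin_mm: float = 10.0,
) -> pd.DataFrame:
    """Volume-recovery grid: one sphere per phantom, every method applied.

    Returns a long-format table with columns method, diameter_mm, lbr, seed,
    true_cm3, recovered_cm3, ratio, error.  A method failure on a condition
    is recorded (NaN volume, error message) rather than aborting the run.
    """
    if methods is None:
        methods = default_method_registry()
    center = tuple(
        0.5 * (n - 1) * s for n, s in zip(shape, spacing)
    )  # grid-center world position
    rows = []
    for diameter in diameters_mm:
        for lbr in lbrs:
            for seed in seeds:
                spec = PhantomSpec(
                    shape=tuple(shape),
                    spacing=tuple(spacing),
                    background_suv=background_suv,
                    spheres=(SphereSpec(center, diameter, lbr),),
                    psf_fwhm_mm=psf_fwhm_mm,
                    noise_coefficient=noise_coefficient,
                    seed=seed,
                )
                image, truths = generate_phantom(spec)
                true_cm3 = truths[0].volume_cm3
                semi = 0.5 * diameter + voi_margin_mm
                voi = EllipsoidVOI(center=center, semi_axes=(semi, semi, semi))
                for name, fn in methods.items():
                    try:
                        mask = fn(image, voi)
                        recovered = mask.volume_cm3
                        ratio = recovered / true_cm3
                        err = ""
                    except Exception as exc:
                        recovered, ratio, err = np.nan, np.nan, str(exc)
                    rows.append(
                        {
                            "method": name,
                            "diameter_mm": diameter,
                            "lbr": lbr,
                            "seed": seed,
                            "true_cm3": true_cm3,
                            "recovered_cm3": recovered,
                            "ratio": ratio,
                            "error": err,
                        }
                    )
    return pd.DataFrame(rows)


def summarize_recovery(table: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD of the recovery ratio per method x diameter x LBR."""
    return (
        table.groupby(["method", "diameter_mm", "lbr"])["ratio"]
        .agg(ratio_mean="mean", ratio_sd="std", n="count")
        .reset_index()
    )
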