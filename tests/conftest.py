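import numpy as np
import pytest

from mopet import EllipsoidVOI, PhantomSpec, SphereSpec, generate_phantom


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def sharp_sphere_phantom():
    """Noise-free, blur-free sphere (LBR 8:1) with its truth mask and VOI."""
    center = (63.0, 63.0, 63.0)
    spec = PhantomSpec(
        shape=(64, 64, 64),
        spacing=(2.0, 2.0, 2.0),
        background_suv=1.0,
        spheres=(SphereSpec(center=center, diameter_mm=22.0, lbr=8.0),),
        psf_fwhm_mm=0.0,
        noise_coefficient=0.0,
        seed=0,
    )
    image, truths = generate_phantom(spec)
    voi = EllipsoidVOI(center=center, semi_axes=(24.0, 24.0, 24.0))
    return image, truths[0], voi


@pytest.fixture()
def blurred_phantom():
    """Factory for blurred, noisy single-sphere phantoms."""
    return make_blurred_phantom


def make_blurred_phantom(diameter_mm=22.0, lbr=4.0, seed=0, noise=0.10):
    """Blurred (6 mm FWHM), noisy single-sphere phantom on a 2 mm grid."""
    center = (63.0, 63.0, 63.0)
    spec = PhantomSpec(
        shape=(64, 64, 64),
        spacing=(2.0, 2.0, 2.0),
        background_suv=1.0,
        spheres=(SphereSpec(center=center, diameter_mm=diameter_mm, lbr=lbr),),
        psf_fwhm_mm=6.0,
        noise_coefficient=noise,
        seed=seed,
    )
    image, truths = generate_phantom(spec)
    voi = EllipsoidVOI(
        center=center, semi_axes=tuple([diameter_mm / 2 + 10.0] * 3)
    )
    return image, truths[0], voi
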