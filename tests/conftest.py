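import numpy as np
import pytest

from petseg import PhantomSpec, SuvImage


def make_image(values, spacing=(4.0, 4.0, 4.0), origin=(0.0, 0.0, 0.0)) -> SuvImage:
    return SuvImage(np.asarray(values, dtype=float), spacing, origin)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_spec():
    """Scaled-down noisy study: 3 patients on a 40x40x80 grid."""
    return PhantomSpec(
        n_patients=3,
        shape=(40, 40, 80),
        lesions_per_patient=(1, 4),
        lesion_radii_mm=(6.0, 15.0),
        lesion_suv_max=(5.0, 12.0),
        noise_sd=0.05,
        seed=11,
    )


@pytest.fixture
def clean_spec():
    """Noiseless, blur-free study with well-contrasted uniform lesions."""
    return PhantomSpec(
        n_patients=3,
        shape=(40, 40, 80),
        lesions_per_patient=(1, 4),
        lesion_radii_mm=(6.0, 15.0),
        lesion_suv_max=(4.5, 12.0),
        noise_sd=0.0,
        blur_fwhm_earl=0.0,
        blur_fwhm_psf=0.0,
        day2_uptake_jitter=0.0,
        day2_shift_mm=0.0,
        seed=5,
    )
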