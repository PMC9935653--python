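import numpy as np
import pytest

from thalseg import PhantomSpec, ScannerProfile, make_phantom, scaled_spec


@pytest.fixture(scope="session")
def identity_profile():
    """A scanner that changes nothing: no bias, no noise, unit scale/contrast."""
    return ScannerProfile(
        scanner_id="identity",
        bias_amplitude=0.0,
        noise_std=0.0,
        intensity_scale=1.0,
        contrast_gamma=1.0,
    )


@pytest.fixture(scope="session")
def small_spec():
    """32^3 phantom geometry (default anatomy scaled down)."""
    return scaled_spec((32, 32, 32))


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def clean_phantom(default_spec, identity_profile):
    """One 64^3 phantom rendered without any scanner distortion."""
    return make_phantom(default_spec, identity_profile, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
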