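"""Shared fixtures: small, fast phantoms reused across test modules."""

import numpy as np
import pytest

from radiogen.phantom import PhantomSpec, generate_lesion_phantom


@pytest.fixture(scope="session")
def clean_sphere_phantom():
    """Noiseless homogeneous spherical lesion on a compact grid."""
    spec = PhantomSpec(
        grid_shape=(48, 48, 32),
        lesion_radius=7.0,
        kinetic_type="plateau",
        peak_enhancement=1.0,
        heterogeneity_sd=0.0,
        noise_sd=0.0,
    )
    series, mask = generate_lesion_phantom(spec, rng_seed=42)
    return spec, series, mask


@pytest.fixture(scope="session")
def heterogeneous_phantom():
    """Washout lesion with heterogeneity and mild noise."""
    spec = PhantomSpec(
        grid_shape=(48, 48, 32),
        lesion_radius=7.0,
        spiculation_amplitude=0.15,
        kinetic_type="washout",
        peak_enhancement=1.2,
        heterogeneity_sd=0.2,
        noise_sd=0.02,
    )
    series, mask = generate_lesion_phantom(spec, rng_seed=7)
    return spec, series, mask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
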