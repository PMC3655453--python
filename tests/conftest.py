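"""Shared fixtures: small phantoms and deterministic RNGs."""

import numpy as np
import pytest

from gdmap import PhantomSpec, generate_scene, simulate_acquisition


@pytest.fixture(scope="session")
def small_spec():
    """A reduced phantom grid that keeps per-test fitting cheap."""
    return PhantomSpec(
        shape=(48, 48, 10),
        leg_center=(7.0, 7.0),
        leg_semiaxes=(6.6, 6.6),
        femur_center=(3.6, 7.0),
        femur_outer_radius=1.6,
        canal_radius=1.0,
        rod_center=(10.0, 7.0),
        rod_radius=1.0,
        rod_slices=(3, 8),
        r_max=3.4,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def quiet_scene(small_spec):
    """Noise-free scene with minimal native spread (discretization-only regime)."""
    import dataclasses

    spec = dataclasses.replace(
        small_spec, noise_sigma=0.0, muscle_t1_sd=25.0, canal_t1_sd=25.0
    )
    return generate_scene(spec, seed=11)


@pytest.fixture(scope="session")
def quiet_series(quiet_scene):
    return simulate_acquisition(quiet_scene, seed=12)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
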