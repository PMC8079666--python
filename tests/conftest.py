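import numpy as np
import pytest

from fdm3pool.signal_model import ThreePoolParams, make_te_schedule
from fdm3pool.synthetic_mgre import (
    NuisanceSpec,
    PhantomSpec,
    generate_phantom,
    simulate_acquisition,
)


@pytest.fixture(scope="session")
def schedule():
    """The acquisition TE grid: 25 bipolar echoes, 1.62 / 1.23 ms."""
    return make_te_schedule(1.62, 1.23, 25)


@pytest.fixture(scope="session")
def seg3_params():
    """Posterior-segment mean tissue parameters (generating truth)."""
    return ThreePoolParams.from_hz(
        f_m=0.16,
        f_a=0.42,
        f_e=0.42,
        omega_m_hz=27.3,
        omega_a_hz=-8.5,
        r2s_m=150.0,
        r2s_a=0.0,
        r2s_e=25.0,
    )


@pytest.fixture(scope="session")
def small_phantom_spec():
    """A reduced 96x96 phantom that keeps the full arc geometry."""
    return PhantomSpec(grid=(96, 96), arc_radii_px=(33.0, 15.0))


@pytest.fixture(scope="session")
def small_phantom(small_phantom_spec):
    return generate_phantom(small_phantom_spec, seed=11)


@pytest.fixture(scope="session")
def noiseless_stack(small_phantom, schedule):
    """Full-nuisance, noise-free two-channel acquisition of the small phantom."""
    nuisance = NuisanceSpec(n_channels=2, noise_sigma=0.0)
    return simulate_acquisition(small_phantom, nuisance, schedule, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
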