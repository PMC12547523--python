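import numpy as np
import pytest

from thermokin import (
    HeatingProgram,
    KineticTriplet,
    NoiseSpec,
    add_noise,
    compute_conversion,
    conversion_to_thermogram,
    simulate_conversion,
)

BETAS = (10.0, 20.0, 30.0, 40.0)


@pytest.fixture(scope="session")
def ref_triplet():
    """First-order reference kinetics used by the simulator oracles."""
    return KineticTriplet(Ea=120e3, A=1e10)


@pytest.fixture(scope="session")
def study_triplet():
    """Kinetics of the default parameter-recovery scenario."""
    return KineticTriplet(Ea=105e3, A=1e9)


@pytest.fixture(scope="session")
def study_sim_curves(study_triplet):
    """Noiseless simulated conversion curves at the four heating rates."""
    return [
        simulate_conversion(study_triplet, HeatingProgram(beta=b)) for b in BETAS
    ]


@pytest.fixture(scope="session")
def study_thermograms(study_sim_curves):
    return [conversion_to_thermogram(c) for c in study_sim_curves]


@pytest.fixture(scope="session")
def study_curves(study_thermograms):
    """Curves recovered from the noiseless thermograms (round trip)."""
    return [compute_conversion(tg) for tg in study_thermograms]


@pytest.fixture(scope="session")
def noisy_curves(study_thermograms):
    """Curves recovered after 0.2% multiplicative mass noise."""
    return [
        compute_conversion(add_noise(tg, NoiseSpec(mass_noise_sd=0.002, seed=100 + k)))
        for k, tg in enumerate(study_thermograms)
    ]


@pytest.fixture(scope="session")
def alpha_grid():
    return np.arange(0.10, 0.801, 0.05)
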