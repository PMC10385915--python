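import numpy as np
import pytest

from fdcare.multistate import IntensityModel, build_Q, chain_structure
from fdcare.states import AGE_BANDS, SEXES
from fdcare.synthetic import SimConfig, generate_cohort

#: moderate chain intensities used as simulation ground truth in the tests
TEST_RATES = {
    (4, 5): 0.45, (5, 4): 0.18,
    (5, 2): 0.20, (2, 5): 0.30,
    (2, 3): 0.35, (3, 2): 0.30,
    (3, 1): 0.15, (1, 3): 0.25,
    (1, 6): 0.10, (2, 6): 0.06, (3, 6): 0.08, (4, 6): 0.02, (5, 6): 0.04,
}


@pytest.fixture(scope="session")
def chain():
    return chain_structure()


@pytest.fixture(scope="session")
def true_model(chain):
    theta = np.array([np.log(TEST_RATES[t]) for t in chain.transitions])
    return IntensityModel(chain, theta)


@pytest.fixture(scope="session")
def true_Q(true_model):
    return build_Q(true_model)


def make_panel(Q, n, seed, wave_times=(0.0, 2.0, 4.0),
               init=(0.1, 0.1, 0.1, 0.35, 0.35)):
    """Homogeneous-stratum panel simulated under one generator matrix."""
    cfg = SimConfig(
        n_individuals=n,
        wave_times=list(wave_times),
        sex_proportion_female=0.5,
        age_band_proportions={"60-69": 0.6, "70+": 0.4},
        true_intensities={(s, b): Q for s in SEXES for b in AGE_BANDS},
        initial_state_distribution={
            (s, b): np.asarray(init, dtype=float) for s in SEXES for b in AGE_BANDS
        },
        seed=seed,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def panel_2000(true_Q):
    return make_panel(true_Q, 2000, seed=42)
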