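import numpy as np
import pytest

from aesthdyn import SimulationConfig, simulate_experiment
from aesthdyn.config import Dist
from aesthdyn.synth import ParticipantProfile, StimulusProfile


def make_profile(**kw) -> ParticipantProfile:
    base = dict(participant_id="P000", group="rate", w_shared=0.5,
                tau_integration=1.0, dead_zone=0.05, session_noise_sd=0.1,
                overall_noise_sd=0.05)
    base.update(kw)
    return ParticipantProfile(**base)


def make_stimulus(**kw) -> StimulusProfile:
    base = dict(stimulus_id="D00", category="dance", mean_level=0.1,
                length_scale_s=3.0, amplitude=0.4, category_mean_shift=-0.1)
    base.update(kw)
    return StimulusProfile(**base)


def constant_population(**overrides) -> dict:
    """Population where every parameter is a point mass (easy degenerate cases)."""
    pop = {
        "w_shared": Dist("constant", (0.5,)),
        "tau_integration": Dist("constant", (0.8,)),
        "dead_zone": Dist("constant", (0.03,)),
        "session_noise_sd": Dist("constant", (0.15,)),
        "overall_noise_sd": Dist("constant", (0.08,)),
        "mean_bias": Dist("constant", (0.0,)),
        "affinity": Dist("constant", (0.0,)),
    }
    for k, v in overrides.items():
        pop[k] = v if isinstance(v, Dist) else Dist("constant", (float(v),))
    return pop


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_rate=6, n_view=6, n_dance=5, n_landscape=5,
                            rng_seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_experiment(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size simulated experiment (25+25 observers, 15+15 clips)."""
    return simulate_experiment(SimulationConfig(rng_seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
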