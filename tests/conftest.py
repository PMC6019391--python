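import numpy as np
import pytest

import satrace
from satrace import ConditionParams, ModelParameters, SimConfig, make_parameters


@pytest.fixture(scope="session")
def tms_params() -> ModelParameters:
    """Group-level TMS-session estimates (time normalized to median RT)."""
    return satrace.TMS_STUDY_PARAMS


@pytest.fixture(scope="session")
def eeg_params() -> ModelParameters:
    return satrace.EEG_STUDY_PARAMS


@pytest.fixture(scope="session")
def small_params() -> ModelParameters:
    """A fast-deciding parameter set for cheap simulations."""
    return make_parameters(
        a_speed=0.8, sz_accuracy=0.3, sz_speed=0.4,
        v_correct_easy=2.0, v_correct_hard=1.0,
        v_incorrect_easy=0.4, v_incorrect_hard=0.2,
        noise_sd=0.6, t_er=0.3, s_ter=0.2,
    )


@pytest.fixture(scope="session")
def quick_sim() -> SimConfig:
    return SimConfig(dt=0.01, max_time=5.0, n_trials=2000, seed=7)


@pytest.fixture(scope="session")
def noiseless_cell() -> ConditionParams:
    return ConditionParams(boundary=1.0, start_range=0.0, drift_correct=10.0,
                           drift_incorrect=0.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def tms_trials_small(tms_params):
    """2,000 trials/cell at the TMS estimates; shared across tests."""
    design = [(i, d, 2000) for i in ("accuracy", "speed")
              for d in ("easy", "hard")]
    return satrace.simulate_dataset(tms_params, design,
                                    SimConfig(0.01, 5.0, 2000, 42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
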