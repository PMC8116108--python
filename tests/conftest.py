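import numpy as np
import pytest

from soundpursuit import (
    APSParameters,
    SumOfSinesSpec,
    SyntheticSubjectConfig,
    generate_stimulus,
    simulate_session,
    simulate_trial,
    trial_set,
)


@pytest.fixture(scope="session")
def spec():
    return SumOfSinesSpec()


@pytest.fixture(scope="session")
def stimulus(spec):
    return generate_stimulus(spec, seed=1234)


@pytest.fixture(scope="session")
def noise_free_trial(spec, stimulus):
    """One noise-free trial of a mid-damping subject with a 50 ms delay."""
    params = APSParameters(f_c=0.6, zeta=0.5, t_d=0.050)
    return simulate_trial(stimulus, params, noise_sd=0.0, spec=spec)


@pytest.fixture(scope="session")
def noise_free_session(spec):
    """A short noise-free session (8 trials) with the default Q drift."""
    stims = trial_set(8, spec, seed=77)
    cfg = SyntheticSubjectConfig(t_d=0.050, noise_sd=0.0, q_jitter_sd=0.0)
    return simulate_session(cfg, stims, seed=78, spec=spec)


@pytest.fixture(scope="session")
def noisy_session(spec):
    """A short session (6 trials) at the default 1 deg measurement noise."""
    stims = trial_set(6, spec, seed=99)
    cfg = SyntheticSubjectConfig(t_d=0.030, noise_sd=1.0, q_jitter_sd=0.15)
    return simulate_session(cfg, stims, seed=100, spec=spec)
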