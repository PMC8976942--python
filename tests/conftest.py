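import numpy as np
import pytest

from thermoresp import CalibrationConstants
from thermoresp.simulate import (
    BreathModelParams,
    ConditionParams,
    LogNormalSpec,
    simulate_trace,
)


@pytest.fixture
def calib():
    """Default calibration constants (standard Planck/atmosphere values)."""
    return CalibrationConstants()


@pytest.fixture
def fixed_cycle_params():
    """Deterministic 0.6 s / 0.5 s / 0.9 s cycles with fixed amplitudes."""
    cond = ConditionParams(
        insp_duration_s=LogNormalSpec(0.6),
        exp_duration_s=LogNormalSpec(0.5),
        pause_duration_s=LogNormalSpec(0.9),
        insp_amplitude_C=LogNormalSpec(0.94),
        exp_amplitude_C=LogNormalSpec(0.78),
        pause_amplitude_C=LogNormalSpec(0.16),
    )
    return BreathModelParams(noise_sd_C=0.0, conditions={"Quiet": cond})


@pytest.fixture
def noiseless_trace(fixed_cycle_params):
    trace, gt = simulate_trace(fixed_cycle_params, 8, seed=1)
    return trace, gt


@pytest.fixture
def quiet_trace():
    """A default-condition Quiet trace with sensor noise."""
    trace, gt = simulate_trace(BreathModelParams(), 40, seed=11)
    return trace, gt


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
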