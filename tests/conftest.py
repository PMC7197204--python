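import numpy as np
import pytest

from hdclamp import (HumanParams, OscState, TrialConfig, VPParams,
                     make_schedule, simulate_session)


@pytest.fixture(scope="session")
def vp_params() -> VPParams:
    return VPParams()


@pytest.fixture(scope="session")
def uncoupled_trajectory(vp_params):
    """60-s uncoupled VP run used by several frequency/limit-cycle tests."""
    from hdclamp import simulate_vp
    return simulate_vp(None, vp_params, OscState(0.1, 0.0), n_steps=30000)


@pytest.fixture(scope="session")
def small_session():
    """One simulated 8-trial session (all four trial types, both tasks)."""
    configs = make_schedule(8, 4, seed=11)
    records = simulate_session(configs, HumanParams(), VPParams(), seed=11)
    return records
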