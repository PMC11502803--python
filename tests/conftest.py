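import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ctdphase as cp

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_params():
    return cp.InteractionParams.default()


@pytest.fixture(scope="session")
def water_params():
    """Aqueous-dielectric parameters for closed-form electrostatics checks."""
    return cp.InteractionParams(
        type_eps={"Y": 9.5, "S": 1.0, "P": 1.0, "T": 1.0},
        dielectric=78.5,
    )


@pytest.fixture(scope="session")
def small_condensate(default_params):
    """A short 5-chain condensed-phase run shared by clustering tests."""
    seq = cp.build_ctd("cons", 2)
    top = cp.build_topology(seq, default_params)
    system = cp.System([top] * 5, default_params)
    cfg = cp.SimulationConfig(box=(8.0, 8.0, 8.0), n_steps=3000, seed=33,
                              save_every=150, friction=0.15)
    traj = cp.run_dynamics(system, cfg)
    return traj
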