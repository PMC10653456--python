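import numpy as np
import pytest

from ecosocnet import (
    IntegratorSettings,
    ModelParams,
    alpha_star,
    integrate_rk4,
    resolved_alpha_crit,
    run_chaos_scenario,
)


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def a_star(params):
    return alpha_star(params)


@pytest.fixture(scope="session")
def a_crit(params):
    return resolved_alpha_crit(params)


@pytest.fixture(scope="session")
def limit_cycle_traj(params, a_crit):
    """Post-transient single-system run on the large limit cycle (2 alpha_c)."""
    return integrate_rk4(
        params.with_alpha(2 * a_crit),
        settings=IntegratorSettings(dt=0.05, t_end=20000.0, burn_in=12000.0, stride=4),
    )


@pytest.fixture(scope="session")
def fixed_point_traj(params, a_star):
    """Single-system run converging to the interior equilibrium (2 alpha_star)."""
    return integrate_rk4(
        params.with_alpha(2 * a_star),
        settings=IntegratorSettings(dt=0.05, t_end=5000.0, burn_in=0.0, stride=4),
    )


@pytest.fixture(scope="session")
def chaos_bundle():
    """The three-node perturbed-uniform-interaction chaos scenario."""
    return run_chaos_scenario(seed=0)
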