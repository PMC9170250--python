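import numpy as np
import pandas as pd
import pytest

from causalcue import (
    FitConfig,
    ObserverParams,
    QuadratureSpec,
    make_schedule_exp1,
    make_schedule_exp2,
    simulate_observer,
)


@pytest.fixture(scope="session")
def default_params():
    return ObserverParams()


@pytest.fixture(scope="session")
def quad():
    """Accurate-but-fast quadrature for tests."""
    return QuadratureSpec(order=41, bisect_iters=50)


@pytest.fixture(scope="session")
def fast_config():
    """Single-start fitting config used where the likelihood is well-behaved."""
    return FitConfig(n_starts=1, maxiter=150)


@pytest.fixture(scope="session")
def exp1_schedule():
    return make_schedule_exp1(seed=0)


@pytest.fixture(scope="session")
def exp2_schedule():
    return make_schedule_exp2(seed=0)


@pytest.fixture(scope="session")
def joint_dataset(exp1_schedule, exp2_schedule):
    """One simulated subject with exp1 + exp2 data at study trial counts."""
    params = ObserverParams(p_common=0.5)
    sched = pd.concat([exp1_schedule, exp2_schedule], ignore_index=True)
    return simulate_observer(sched, params, seed=1234), params


def random_observer_params(rng, tight=False):
    """Moderate random parameter draws for oracle comparisons."""
    return ObserverParams(
        sigma_a=rng.uniform(1.0, 10.0),
        sigma_v={
            "high": rng.uniform(0.5, 3.0),
            "medium": rng.uniform(3.0, 8.0),
            "low": rng.uniform(8.0, 18.0),
        },
        mu_a_prior=rng.normal(0.0, 3.0),
        sigma_a_prior=rng.uniform(8.0, 40.0),
        mu_v_prior=rng.normal(0.0, 3.0),
        sigma_v_prior=rng.uniform(8.0, 40.0),
        p_common=rng.uniform(0.05, 0.95),
        p_choice_implicit=0.5 if tight else rng.uniform(0.2, 0.8),
        p_combined=rng.uniform(0.05, 0.95),
        lapse_rate=0.0,
        lapse_bias=0.5,
    )
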