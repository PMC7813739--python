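import pytest
from hypothesis import HealthCheck, settings

from mrm_cea import Conventions, TKParameters

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Project-wide fixed seed for stochastic checks.
SEED = 0


def random_markov_spec(rng, n_states: int = 3, with_transition_costs: bool = False):
    """A random valid cohort spec with one absorbing dead state (last)."""
    import numpy as np

    from mrm_cea.markov import MarkovSpec

    states = tuple(f"s{i}" for i in range(n_states - 1)) + ("dead",)
    matrix = rng.dirichlet(np.ones(n_states), size=n_states)
    matrix[-1] = 0.0
    matrix[-1, -1] = 1.0

    costs = rng.uniform(0, 5000, size=n_states)
    costs[-1] = 0.0
    utilities = rng.uniform(0, 1, size=n_states)
    utilities[-1] = 0.0
    transition_costs = None
    if with_transition_costs:
        frm, to = rng.choice(n_states - 1, size=2, replace=True)
        transition_costs = {(states[frm], states[to]): float(rng.uniform(0, 8000))}
    return MarkovSpec(
        states=states,
        transitions=lambda cycle: matrix,
        state_costs=costs,
        state_utilities=utilities,
        transition_costs=transition_costs,
    )


@pytest.fixture
def params() -> TKParameters:
    return TKParameters()


@pytest.fixture
def conventions() -> Conventions:
    return Conventions()
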