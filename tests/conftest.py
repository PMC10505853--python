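import numpy as np
import pytest

from homodiff import Group, ModelConfig, PopulationState, StartCondition, Trait


@pytest.fixture
def worked_example():
    """The seven-agent illustration of the learning rule.

    Three minority agents (one adaptive), four majority agents (two
    adaptive), f(a) = 1.2, f(A) = 1.0, h_min = 0.2, h_maj = 0.6.
    Returns (config, state, non-adaptive minority learner index,
    non-adaptive majority learner index).
    """
    config = ModelConfig(
        N=7, m=3 / 7, h_min=0.2, h_maj=0.6, f_a=1.2, f_A=1.0,
        start_condition=StartCondition.MINORITY, seed=0,
    )
    group_of = np.array([0, 0, 0, 1, 1, 1, 1], dtype=np.int8)
    trait_of = np.array([1, 0, 0, 1, 1, 0, 0], dtype=np.int8)
    state = PopulationState(group_of=group_of, trait_of=trait_of, step=0)
    return config, state, 1, 5


def make_state(config: ModelConfig, n_min: int, n_maj: int) -> PopulationState:
    """Population with the first n adopters of each group adaptive."""
    s_min = config.s_min
    group_of = np.empty(config.N, dtype=np.int8)
    group_of[:s_min] = Group.MINORITY
    group_of[s_min:] = Group.MAJORITY
    trait_of = np.full(config.N, Trait.NON_ADAPTIVE, dtype=np.int8)
    trait_of[:n_min] = Trait.ADAPTIVE
    trait_of[s_min:s_min + n_maj] = Trait.ADAPTIVE
    return PopulationState(group_of=group_of, trait_of=trait_of, step=0)
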