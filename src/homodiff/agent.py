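"""Agent-level engine: explicit agents, synchronous homophilous learning.

Each round, every agent independently selects one teacher (never itself):
with probability ``(1 + h)/2`` from its own group, else from the other
group, and within the chosen pool with probability proportional to the
fitness of the prospective teacher's trait.  All agents then adopt their
teacher's *pre-round* trait simultaneously, so the order in which agents
are processed within a round is irrelevant.

This module is the literal, per-agent implementation.  The distributionally
identical count-level engine in :mod:`homodiff.counts` is faster and serves
as its verification oracle (and vice versa).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .types import (
    ConfigError,
    Group,
    ModelConfig,
    StartCondition,
    Trait,
    TrialResult,
    trial_rng,
)

__all__ = [
    "PopulationState",
    "init_population",
    "in_group_prob",
    "out_group_prob",
    "teacher_distribution",
    "conditional_adoption_prob",
    "adoption_prob",
    "step_synchronous",
    "run_trial",
]


@dataclass
class PopulationState:
    """Per-agent group labels and traits at round ``step``.

    ``group_of`` is fixed for a trial; only ``trait_of`` evolves.
    """

    group_of: np.ndarray  # int8, Group values, length N
    trait_of: np.ndarray  # int8, Trait values, length N
    step: int = 0

    @property
    def N(self) -> int:
        return len(self.group_of)

    def adopter_counts(self) -> tuple[int, int]:
        """(minority adopters, majority adopters)."""
        adaptive = self.trait_of == Trait.ADAPTIVE
        minority = self.group_of == Group.MINORITY
        return int(np.sum(adaptive & minority)), int(np.sum(adaptive & ~minority))

    def is_absorbing(self) -> bool:
        first = self.trait_of[0]
        return bool(np.all(self.trait_of == first))


def in_group_prob(h: float) -> float:
    """Probability that a learner samples its teacher from its own group.

    ``(1 + h) / 2`` for homophily ``h`` in [0, 1]; 0.5 at indifference,
    1 at full homophily.
    """
    if not (0.0 <= h <= 1.0):
        raise ConfigError(f"homophily must lie in [0, 1], got {h}")
    return (1.0 + h) / 2.0


def out_group_prob(h: float) -> float:
    """Probability of sampling the teacher from the other group, ``(1 - h)/2``."""
    if not (0.0 <= h <= 1.0):
        raise ConfigError(f"homophily must lie in [0, 1], got {h}")
    return (1.0 - h) / 2.0


def init_population(
    config: ModelConfig, rng: Optional[np.random.Generator] = None
) -> PopulationState:
    """Build the round-0 population for ``config``.

    Agents ``0..s_min-1`` are minority, the rest majority.  Exactly one
    agent in the designated start group (one in each for ``both``) holds
    the adaptive trait; its position within the group is drawn uniformly
    (within-group exchangeability makes the position inconsequential, but
    a random draw keeps the trial fully seed-driven).
    """
    if rng is None:
        rng = trial_rng(config.seed)
    s_min, N = config.s_min, config.N
    group_of = np.empty(N, dtype=np.int8)
    group_of[:s_min] = Group.MINORITY
    group_of[s_min:] = Group.MAJORITY
    trait_of = np.full(N, Trait.NON_ADAPTIVE, dtype=np.int8)
    start = config.start_condition
    if start in (StartCondition.MINORITY, StartCondition.BOTH):
        trait_of[rng.integers(s_min)] = Trait.ADAPTIVE
    if start in (StartCondition.MAJORITY, StartCondition.BOTH):
        trait_of[s_min + rng.integers(N - s_min)] = Trait.ADAPTIVE
    return PopulationState(group_of=group_of, trait_of=trait_of, step=0)


def _pool_counts(
    state: PopulationState, learner: int, source: str
) -> tuple[int, int]:
    """(adaptive, non-adaptive) teacher counts in the learner's in/out pool."""
    g = state.group_of[learner]
    if source == "in":
        mask = state.group_of == g
    elif source == "out":
        mask = state.group_of != g
    else:
        raise ValueError(f"source must be 'in' or 'out', got {source!r}")
    adaptive = int(np.sum(mask & (state.trait_of == Trait.ADAPTIVE)))
    total = int(np.sum(mask))
    if source == "in":
        total -= 1  # self-learning is not allowed
        if state.trait_of[learner] == Trait.ADAPTIVE:
            adaptive -= 1
    if total < 1:
        raise ConfigError(
            "learner's in-group pool is empty (group of size 1); "
            "configurations require every group size >= 2"
        )
    return adaptive, total - adaptive


def conditional_adoption_prob(
    state: PopulationState, learner: int, source: str, config: ModelConfig
) -> float:
    """P(newly learned trait is adaptive | teacher pool), pool = ``"in"``/``"out"``.

    The fitness-weighted share of adaptive teachers in the pool, the
    learner itself excluded from its in-group pool.
    """
    n_a, n_A = _pool_counts(state, learner, source)
    w = config.f_a * n_a
    return w / (w + config.f_A * n_A)


def adoption_prob(state: PopulationState, learner: int, config: ModelConfig) -> float:
    """Marginal probability the learner's next trait is adaptive.

    Group choice (in with probability ``(1+h)/2``) marginalised over the
    two conditional pool probabilities.
    """
    h = config.homophily(Group(state.group_of[learner]))
    return in_group_prob(h) * conditional_adoption_prob(
        state, learner, "in", config
    ) + out_group_prob(h) * conditional_adoption_prob(state, learner, "out", config)


def teacher_distribution(
    state: PopulationState, learner: int, config: ModelConfig
) -> np.ndarray:
    """Probability that each agent is chosen as the learner's teacher.

    For teacher ``j`` in the learner's group ``G`` the probability is
    ``(1+h_G)/2 * f(T_j) / sum_{k != learner, k in G} f(T_k)``; for ``j``
    in the other group it is ``(1-h_G)/2 * f(T_j) / sum_{k in G'} f(T_k)``.
    ``P(learner) = 0`` and the vector sums to 1.
    """
    if not (0 <= learner < state.N):
        raise IndexError(f"learner index {learner} out of range")
    g = state.group_of[learner]
    h = config.homophily(Group(g))
    fit = np.where(state.trait_of == Trait.ADAPTIVE, config.f_a, config.f_A)
    in_mask = state.group_of == g
    in_mask_pool = in_mask.copy()
    in_mask_pool[learner] = False
    if not in_mask_pool.any():
        raise ConfigError(
            "learner's in-group pool is empty (group of size 1); "
            "configurations require every group size >= 2"
        )
    out_mask = ~in_mask
    probs = np.zeros(state.N)
    probs[in_mask_pool] = in_group_prob(h) * fit[in_mask_pool] / fit[in_mask_pool].sum()
    probs[out_mask] = out_group_prob(h) * fit[out_mask] / fit[out_mask].sum()
    return probs


def step_synchronous(
    state: PopulationState, config: ModelConfig, rng: np.random.Generator
) -> PopulationState:
    """Advance one synchronous round; returns a new state, input untouched.

    Teacher sampling is stratified for speed: first the pool (in/out group),
    then the teacher's trait stratum with probability proportional to the
    stratum's total fitness, then a uniform index within the stratum (all
    teachers in a stratum share one fitness, so this equals the per-teacher
    fitness-weighted draw exactly; the uniform within-stratum index draw
    excludes the learner from its own in-group stratum).
    """
    N = state.N
    traits = state.trait_of
    groups = state.group_of
    f_a, f_A = config.f_a, config.f_A

    # per-group stratum index lists on the pre-round snapshot
    strata = {}  # (group, trait) -> index array
    for g in (Group.MINORITY, Group.MAJORITY):
        gm = groups == g
        strata[(int(g), 1)] = np.flatnonzero(gm & (traits == Trait.ADAPTIVE))
        strata[(int(g), 0)] = np.flatnonzero(gm & (traits == Trait.NON_ADAPTIVE))

    u_pool = rng.random(N)
    u_strat = rng.random(N)
    u_idx = rng.random(N)
    p_in = {0: in_group_prob(config.h_min), 1: in_group_prob(config.h_maj)}

    new_traits = np.empty(N, dtype=np.int8)
    for i in range(N):
        g = int(groups[i])
        t = int(traits[i])
        pool_g = g if u_pool[i] < p_in[g] else 1 - g
        own = pool_g == g
        n_a = len(strata[(pool_g, 1)]) - (own and t == 1)
        n_A = len(strata[(pool_g, 0)]) - (own and t == 0)
        if n_a + n_A < 1:
            raise ConfigError(
                "empty teacher pool (group of size 1); "
                "configurations require every group size >= 2"
            )
        w_a = f_a * n_a
        teach_adaptive = u_strat[i] < w_a / (w_a + f_A * n_A)
        stratum = strata[(pool_g, 1 if teach_adaptive else 0)]
        # uniform index among stratum members, excluding self if present
        if own and t == (1 if teach_adaptive else 0):
            k = int(u_idx[i] * (len(stratum) - 1))
            teacher = stratum[k] if stratum[k] != i else stratum[-1]
        else:
            teacher = stratum[int(u_idx[i] * len(stratum))]
        new_traits[i] = traits[teacher]
    return PopulationState(group_of=groups, trait_of=new_traits, step=state.step + 1)


def run_trial(
    config: ModelConfig,
    rng: Optional[np.random.Generator] = None,
    record_series: bool = False,
) -> TrialResult:
    """Run one trial to fixation (or the censoring cap) with the agent engine.

    The same ``config`` and seed always yield a bit-identical result.
    """
    if rng is None:
        rng = trial_rng(config.seed)
    state = init_population(config, rng)
    series: Optional[list[tuple[int, int, int]]] = None
    if record_series:
        series = [(0, *state.adopter_counts())]
    while state.step < config.max_steps:
        n_min, n_maj = state.adopter_counts()
        n = n_min + n_maj
        if n == 0:
            return TrialResult("failure", state.step, series)
        if n == config.N:
            return TrialResult("success", state.step, series)
        state = step_synchronous(state, config, rng)
        if record_series:
            series.append((state.step, *state.adopter_counts()))
    n_min, n_maj = state.adopter_counts()
    n = n_min + n_maj
    if n == 0:
        return TrialResult("failure", state.step, series)
    if n == config.N:
        return TrialResult("success", state.step, series)
    return TrialResult("censored", state.step, series)
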