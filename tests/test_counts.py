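"""Count-level reduction: class rates, transition matrix, chain solves.

The exactness anchor is a brute-force enumeration of every joint teacher
assignment at s_min = s_maj = 2, built solely from the agent-level teacher
distribution, against which the binomial-convolution transition matrix is
checked entry by entry.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from homodiff import (
    ConfigError,
    CountState,
    ModelConfig,
    StartCondition,
    Trait,
    adoption_prob,
    class_rates,
    count_step,
    count_trial,
    expected_absorption_time,
    fixation_probability,
    single_group_fixation,
    start_counts,
    teacher_distribution,
    transition_matrix,
    trial_rng,
    uniform_encounter_probability,
)
from homodiff.counts import _state_index

from conftest import make_state


# ----------------------------------------------------------------- class rates

def test_class_rates_worked_example(worked_example):
    config, _, _, _ = worked_example
    r = class_rates(CountState(1, 2), config)
    assert r.p_gain_min == pytest.approx(6 / 11, abs=1e-12)
    assert r.p_gain_maj == pytest.approx(0.8 * (2.4 / 3.4) + 0.2 * 0.375, abs=1e-12)


def test_class_rates_monomorphic_bounds():
    config = ModelConfig(N=10, m=0.3, h_min=0.4, h_maj=0.7)
    all_adaptive = class_rates(CountState(3, 7), config)
    assert all_adaptive.p_keep_min == 1.0
    assert all_adaptive.p_keep_maj == 1.0
    none_adaptive = class_rates(CountState(0, 0), config)
    assert none_adaptive.p_gain_min == 0.0
    assert none_adaptive.p_gain_maj == 0.0


def test_class_rates_out_of_bounds_counts():
    config = ModelConfig(N=10, m=0.3)
    with pytest.raises(ConfigError):
        class_rates(CountState(4, 0), config)
    with pytest.raises(ConfigError):
        class_rates(CountState(0, 8), config)


@given(st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=100, deadline=None)
def test_class_rates_reproduce_agent_marginals(seed):
    """For every learner class the count-level rate equals the agent-level
    marginal adoption probability of an agent of that class, exactly."""
    rng = np.random.default_rng(seed)
    s_min = int(rng.integers(2, 6))
    s_maj = s_min + int(rng.integers(0, 4))  # minority never exceeds majority
    N = s_min + s_maj
    config = ModelConfig(
        N=N, m=s_min / N,
        h_min=float(rng.uniform(0, 1)), h_maj=float(rng.uniform(0, 1)),
        f_a=float(rng.uniform(0.5, 2.5)), f_A=float(rng.uniform(0.5, 2.5)),
    )
    n_min = int(rng.integers(0, s_min + 1))
    n_maj = int(rng.integers(0, s_maj + 1))
    state = make_state(config, n_min, n_maj)
    r = class_rates(CountState(n_min, n_maj), config)
    for learner in range(N):
        marginal = adoption_prob(state, learner, config)
        in_min = learner < s_min
        adaptive = state.trait_of[learner] == Trait.ADAPTIVE
        expected = {
            (True, True): r.p_keep_min,
            (True, False): r.p_gain_min,
            (False, True): r.p_keep_maj,
            (False, False): r.p_gain_maj,
        }[(in_min, bool(adaptive))]
        assert marginal == pytest.approx(expected, abs=1e-12)


# ------------------------------------------------------------------ count step

def test_count_step_absorbing_states_fixed():
    config = ModelConfig(N=9, m=1 / 3, h_min=0.5, h_maj=0.5)
    rng = trial_rng(0)
    assert count_step(CountState(0, 0), config, rng) == CountState(0, 0)
    assert count_step(CountState(3, 6), config, rng) == CountState(3, 6)


def test_count_step_mean_matches_binomial_expectation():
    config = ModelConfig(N=10, m=0.4, h_min=0.3, h_maj=0.6)
    counts = CountState(2, 3)
    r = class_rates(counts, config)
    exp_min = counts.n_min * r.p_keep_min + (config.s_min - counts.n_min) * r.p_gain_min
    exp_maj = counts.n_maj * r.p_keep_maj + (config.s_maj - counts.n_maj) * r.p_gain_maj
    rng = trial_rng(17)
    n_rep = 40_000
    tot_min = tot_maj = 0
    for _ in range(n_rep):
        nxt = count_step(counts, config, rng)
        tot_min += nxt.n_min
        tot_maj += nxt.n_maj
    se_min = np.sqrt(config.s_min / 4 / n_rep)
    se_maj = np.sqrt(config.s_maj / 4 / n_rep)
    assert abs(tot_min / n_rep - exp_min) < 3 * se_min
    assert abs(tot_maj / n_rep - exp_maj) < 3 * se_maj


def test_one_step_count_distribution_matches_agent_engine(worked_example):
    """The joint one-round count distribution of the agent engine matches
    the exact transition-matrix row (chi-squared GOF, alpha = 0.01)."""
    from homodiff import step_synchronous

    config, state, _, _ = worked_example
    T = transition_matrix(config)
    row = T[_state_index(1, 2, config.s_maj)]
    rng = trial_rng(31)
    n_rep = 30_000
    n_states = (config.s_min + 1) * (config.s_maj + 1)
    observed = np.zeros(n_states)
    for _ in range(n_rep):
        out = step_synchronous(state, config, rng)
        n_min, n_maj = out.adopter_counts()
        observed[_state_index(n_min, n_maj, config.s_maj)] += 1
    expected = row * n_rep
    # pool cells with tiny expectation to keep the chi-squared valid
    keep = expected >= 5
    obs = np.append(observed[keep], observed[~keep].sum())
    exp = np.append(expected[keep], expected[~keep].sum())
    chi2 = ((obs - exp) ** 2 / np.where(exp > 0, exp, 1)).sum()
    pvalue = stats.chi2.sf(chi2, df=len(obs) - 1)
    assert pvalue > 0.01


# ----------------------------------------------------------- transition matrix

def _enumerated_transition_matrix(config: ModelConfig) -> np.ndarray:
    """Brute-force oracle: enumerate every joint teacher assignment from the
    agent-level teacher distributions and project onto counts."""
    s_min, s_maj = config.s_min, config.s_maj
    n_states = (s_min + 1) * (s_maj + 1)
    T = np.zeros((n_states, n_states))
    for n_min in range(s_min + 1):
        for n_maj in range(s_maj + 1):
            state = make_state(config, n_min, n_maj)
            dists = [
                teacher_distribution(state, i, config) for i in range(config.N)
            ]
            teachers_per_agent = [np.flatnonzero(d > 0) for d in dists]
            row = _state_index(n_min, n_maj, s_maj)
            for combo in itertools.product(*teachers_per_agent):
                prob = 1.0
                for i, j in enumerate(combo):
                    prob *= dists[i][j]
                new_traits = state.trait_of[list(combo)]
                nm = int(np.sum(new_traits[:s_min]))
                nM = int(np.sum(new_traits[s_min:]))
                T[row, _state_index(nm, nM, s_maj)] += prob
    return T


def test_transition_matrix_matches_enumeration_s2():
    config = ModelConfig(
        N=4, m=0.5, h_min=0.3, h_maj=0.7, f_a=1.2, f_A=1.0
    )
    T = transition_matrix(config)
    T_brute = _enumerated_transition_matrix(config)
    assert np.max(np.abs(T - T_brute)) < 1e-12


def test_transition_matrix_rows_stochastic():
    config = ModelConfig(N=12, m=1 / 3, h_min=0.6, h_maj=0.2)
    T = transition_matrix(config)
    assert np.allclose(T.sum(axis=1), 1.0, atol=1e-10)
    assert np.all(T >= 0)
    for n_min, n_maj in [(0, 0), (config.s_min, config.s_maj)]:
        i = _state_index(n_min, n_maj, config.s_maj)
        unit = np.zeros(T.shape[0])
        unit[i] = 1.0
        assert np.allclose(T[i], unit, atol=1e-14)


def test_transition_matrix_state_cap():
    config = ModelConfig(N=1000, m=0.05)
    with pytest.raises(ConfigError, match="Monte-Carlo"):
        transition_matrix(config)


# ---------------------------------------------------------------- chain solves

def test_fixation_probability_trivial_starts():
    config = ModelConfig(N=8, m=0.5, h_min=0.4, h_maj=0.4)
    assert fixation_probability(config, CountState(4, 4)) == 1.0
    assert fixation_probability(config, CountState(0, 0)) == 0.0


@pytest.mark.parametrize("N", [4, 6, 8])
def test_neutral_fixation_is_one_over_N(N):
    """Neutral drift with symmetric groups: the adopter count is a
    martingale, so a single adopter fixates with probability exactly 1/N."""
    config = ModelConfig(
        N=N, m=0.5, h_min=0.35, h_maj=0.35, f_a=1.0, f_A=1.0,
        start_condition="minority",
    )
    p = fixation_probability(config)
    assert p == pytest.approx(1.0 / N, abs=1e-8)


def test_neutral_martingale_scales_with_initial_adopters():
    config = ModelConfig(N=6, m=0.5, h_min=0.2, h_maj=0.2, f_a=1.0, f_A=1.0)
    for k_min, k_maj in [(1, 1), (2, 0), (2, 3)]:
        p = fixation_probability(config, CountState(k_min, k_maj))
        assert p == pytest.approx((k_min + k_maj) / 6, abs=1e-8)


def test_full_homophily_product_rule():
    """At h_min = h_maj = 1 with one adopter in each group, the groups
    evolve independently and the metapopulation fixation probability is
    the product of the two isolated single-group probabilities."""
    config = ModelConfig(
        N=7, m=3 / 7, h_min=1.0, h_maj=1.0, f_a=1.2, f_A=1.0,
        start_condition="both",
    )
    joint = fixation_probability(config)
    p_min = single_group_fixation(3, 1, 1.2, 1.0)
    p_maj = single_group_fixation(4, 1, 1.2, 1.0)
    assert joint == pytest.approx(p_min * p_maj, abs=1e-10)
    assert 0 < joint < 1


def test_single_group_fixation_bounds():
    assert single_group_fixation(5, 0, 1.2, 1.0) == 0.0
    assert single_group_fixation(5, 5, 1.2, 1.0) == 1.0
    # neutral single group: martingale gives k/s
    assert single_group_fixation(6, 2, 1.0, 1.0) == pytest.approx(2 / 6, abs=1e-8)


def test_expected_absorption_time_zero_at_absorbing():
    config = ModelConfig(N=8, m=0.5, h_min=0.4, h_maj=0.4)
    assert expected_absorption_time(config, CountState(0, 0)) == 0.0
    assert expected_absorption_time(config, CountState(4, 4)) == 0.0


def test_expected_absorption_time_matches_monte_carlo():
    config = ModelConfig(
        N=8, m=3 / 8, h_min=0.5, h_maj=0.5, f_a=1.2, f_A=1.0,
        start_condition="minority",
    )
    exact = expected_absorption_time(config)
    n_rep = 20_000
    steps = np.array([
        count_trial(config, trial_rng(13, k)).steps for k in range(n_rep)
    ])
    se = steps.std(ddof=1) / np.sqrt(n_rep)
    assert abs(steps.mean() - exact) < 3 * se


def test_absorption_slows_as_selection_weakens():
    """From a mid-prevalence state, expected time to fixation rises
    monotonically as f_a falls toward f_A (drift is slower than selection).

    From a single-adopter start the unconditional time is not monotone —
    weak selection also converts slow successes into fast failures — so
    the clean selection-speed statement is made at interior prevalence;
    the published inverse correlation of time-to-fixation with f_a is
    checked at the experiment level on steps-to-success."""
    config = ModelConfig(N=10, m=0.3, h_min=0.5, h_maj=0.5)
    start = CountState(2, 3)
    times = [
        expected_absorption_time(config.replace(f_a=f_a), start)
        for f_a in (2.0, 1.4, 1.2, 1.05)
    ]
    assert all(a < b for a, b in zip(times, times[1:]))


def test_incubator_asymmetry_exact():
    """With a small minority and an advantageous trait, a single minority
    adopter fixates at least as often as a single majority adopter."""
    config = ModelConfig(N=12, m=0.25, h_min=0.5, h_maj=0.5, f_a=1.2)
    p_minority = fixation_probability(config, CountState(1, 0))
    p_majority = fixation_probability(config, CountState(0, 1))
    assert p_minority >= p_majority


# ------------------------------------------------------------------ MC engine

def test_count_trial_reproducible():
    config = ModelConfig(N=30, m=0.2, h_min=0.6, h_maj=0.6, seed=4)
    a = count_trial(config, record_series=True)
    b = count_trial(config, record_series=True)
    assert (a.outcome, a.steps, a.series) == (b.outcome, b.steps, b.series)


def test_count_trial_neutral_quarter():
    """Neutral drift, N = 4, single minority adopter: success in one
    quarter of trials (martingale), checked within 3 binomial SE."""
    config = ModelConfig(
        N=4, m=0.5, h_min=0.3, h_maj=0.3, f_a=1.0, f_A=1.0,
        start_condition="minority",
    )
    n_rep = 20_000
    wins = sum(count_trial(config, trial_rng(9, k)).success for k in range(n_rep))
    se = np.sqrt(0.25 * 0.75 / n_rep)
    assert abs(wins / n_rep - 0.25) < 3 * se


def test_count_trial_start_override_hook():
    config = ModelConfig(N=50, m=0.2, h_min=0.5, h_maj=0.5)
    full = CountState(config.s_min, config.s_maj)
    res = count_trial(config, trial_rng(0), start=full)
    assert res.outcome == "success" and res.steps == 0


def test_monte_carlo_matches_exact_fixation_probability():
    """Count-engine success frequency agrees with the absorbing-chain solve
    within 3 binomial SE on a small configuration."""
    config = ModelConfig(
        N=9, m=1 / 3, h_min=0.6, h_maj=0.4, f_a=1.3, f_A=1.0,
        start_condition="minority",
    )
    p = fixation_probability(config)
    n_rep = 10_000
    wins = sum(count_trial(config, trial_rng(21, k)).success for k in range(n_rep))
    se = np.sqrt(p * (1 - p) / n_rep)
    assert abs(wins / n_rep - p) < 3 * se


# ------------------------------------------------------------------- heuristic

@pytest.mark.parametrize("m, expected", [(0.05, 1 / 100), (0.2, 1 / 400)])
def test_uniform_encounter_probability(m, expected):
    config = ModelConfig(N=1000, m=m)
    assert uniform_encounter_probability(config) == pytest.approx(expected, abs=0)


def test_start_counts_follow_condition():
    for start, exp in [("minority", (1, 0)), ("majority", (0, 1)), ("both", (1, 1))]:
        config = ModelConfig(start_condition=start)
        assert start_counts(config) == CountState(*exp)
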