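# Methods

## Model

A metapopulation of `N` agents is partitioned once, at initialization,
into a minority group of size `s_min = round(m·N)` (ties rounded away from
zero; validation reports the realized size and requires both groups to
have at least two members) and a majority of size `N − s_min`. Each agent
carries one of two behavioural traits, adaptive `a` or non-adaptive `A`,
with fitnesses `f_a` and `f_A`.

Rounds are synchronous. Every agent independently selects one teacher:

* **group choice** — its own group with probability `(1 + h)/2`, the other
  group with `(1 − h)/2`, where `h` is the *learner's* group homophily
  (`h_min` or `h_maj`);
* **payoff-biased choice within the pool** — teacher `j` with probability
  proportional to `f(T_j)`; the learner is excluded from its own group's
  pool (no self-learning), never from the out-group pool.

All agents then adopt their teacher's *pre-round* trait simultaneously.
Copying from the pre-round snapshot is essential: naive in-place updating
silently changes the process, and under the snapshot rule the order in
which agents are processed within a round is provably irrelevant. The two
monomorphic states are the only absorbing states (except at full
homophily, see below) and a trial ends at the first one reached.

There is no learning noise, no innovation/mutation, at most two groups,
and no network structure beyond the two-group homophily weights.

## Count-level reduction and exact solves

Agents within a group are exchangeable, so the adopter-count pair
`(n_min, n_maj)` is an exact sufficient statistic. Conditional on the
current counts, each of the four learner classes (group × current trait)
has one adoption probability (`ClassRates`), and one round maps counts to
counts as the sum of four independent binomials. This gives:

* `count_trial` — an O(1)-per-round simulator, distributionally identical
  to the agent engine (the equivalence is tested: exact agreement of the
  class rates with per-agent marginals, a chi-squared fit of the one-round
  joint count distribution, and cross-engine agreement of success rates
  and mean steps at `N = 1000`);
* `transition_matrix` — the full row-stochastic matrix over the
  `(s_min+1)(s_maj+1)` count states, row-major in `(n_min, n_maj)`,
  built from binomial-convolution PMFs (`scipy.stats.binom`, which
  evaluates on the log scale and is exact to double precision at the
  sizes used; rows are asserted to sum to 1 within 1e−10, and the matrix
  is checked entry-by-entry against brute-force enumeration of all joint
  teacher assignments at group sizes 2 + 2);
* `fixation_probability` / `expected_absorption_time` — the standard
  absorbing-chain solves `(I − Q)x = b` restricted to transient states,
  using a dense direct solver (the state cap of 10,000 keeps this
  desk-scale; larger populations use the Monte-Carlo path). Absorbing
  states are detected from the matrix diagonal rather than assumed, so at
  `h_min = h_maj = 1` — where the single-group monomorphic states are
  also absorbing — the solves remain correct, and the both-start fixation
  probability factorizes into the product of the two isolated
  single-group probabilities (`single_group_fixation`), an identity the
  tests assert.

Useful exact anchors, all tested: neutral fitness with symmetric groups
makes the adopter count a martingale, so `k` initial adopters fixate with
probability exactly `k/N`; a single minority adopter fixates at least as
often as a single majority one for a small minority and `f_a > f_A`; and
from mid-prevalence states the expected absorption time increases
monotonically as `f_a` falls toward `f_A`. From a *single-adopter* start
the unconditional absorption time is not monotone in `f_a` — weaker
selection also converts slow successes into fast failures — so the
inverse relation between fitness advantage and time-to-fixation is
checked on the conditional mean steps to success, where it is clean.

## Parameters and defaults

| parameter | meaning | default | grid / values exercised |
|---|---|---|---|
| `N` | metapopulation size | 1000 | small sizes in exact tests |
| `m` | minority fraction | 0.05 | 0.2, 0.35, 0.5 in sensitivity checks |
| `h_min`, `h_maj` | group homophily | — (swept) | `{0.0, 0.05, …, 0.95, 0.99}` |
| `f_A` | non-adaptive fitness | 1.0 | fixed |
| `f_a` | adaptive fitness | 1.2 | 1.05, 1.4, 2.0 in sensitivity checks |
| `start_condition` | seeded group(s) | minority | minority / majority / both |
| `max_steps` | censoring cap | 50,000 | — |

The default homophily grid stops at 0.99 for every start condition:
`h = 1.0` is permitted by the engines (and used for the product-rule
identity) but excluded from default sweeps, since with a single-group
start at full homophily fixation is impossible. The step cap exists only
to guarantee termination in exactly such pathological corners; censored
trials are counted in their own column, excluded from success rates and
step statistics, and flagged loudly — at the default parameter ranges
fixation occurs orders of magnitude before the cap and censoring never
fires.

## Randomness and reproducibility

One root seed governs a batch. Trial `k` of a cell draws from a child
generator derived via `numpy` `SeedSequence` spawn keys from
`(root seed, start index, grid indices, k)`, so every batch and sweep is a
pure function of its spec, independent of execution order or parallelism;
reruns are bit-identical (asserted down to the serialized CSV). The
initial adopter's position within its group is drawn from the same
stream — exchangeability makes the position inconsequential, but drawing
it keeps trials fully seed-driven.

The agent engine samples teachers by stratification: pool, then trait
stratum with probability proportional to the stratum's total fitness,
then a uniform index within the stratum (excluding the learner where it
is present). Since all members of a stratum share one fitness, this
equals the per-teacher payoff-biased draw exactly; the explicit
`teacher_distribution` vector is the readable reference, and the sampler
is tested against it.

## Experiment layer

`run_sweep` produces one tidy row per `(h_min, h_maj, start)` cell:
success/failure/censored counts (which always sum to `n_trials`), the
success rate (censored trials never count as successes), and mean steps
conditional on success and on failure (the unconditional mean is also
emitted for per-cell pooling). `summarize_by_start` exposes both the full
multiset of per-cell success rates and their mean per start condition,
plus each condition's argmax cell. The count engine is the default for
sweeps at `N ≥ 100`; the agent engine is available everywhere for
cross-validation. Prevalence time series (per-trial adopter fraction per
group per round) support the incubation diagnostics — e.g. at
`h = 0.99`, minority-seeded successful trials in which the minority is
fully adaptive many rounds before the majority.

## Problem sizes in the shipped tests and acceptance script

Exact solves run at `N ≤ 15`; Monte-Carlo cross-checks use 10⁴ trials on
small populations and a few hundred trials at `N = 1000`; the sweep
reproductions use 1000 trials per cell (the study's own per-cell trial
count) on coarse homophily grids — 3×3 around (0.75, 0.75) in the test
suite and 5×5 over {0.55, …, 0.95} in `scripts/acceptance.py`, for
minority- and both-start conditions at `m = 0.05` and `m = 0.2`. These
grids bracket the success-rate plateau; the full 21×21×3 sweep is a
one-line `SweepSpec` away and runs in minutes with the count engine.

## What the simulations do and do not show

All data here are generated by the model itself; there is no external
data. The two engines validate each other (independent implementations of
one process), and the Markov-chain solver validates both at small sizes —
but none of this bears on how well the model's assumptions (exactly two
static groups, fixed homophily, global teacher access within groups,
noise-free copying, constant fitnesses) describe any real population.
Success-rate maxima reported at desk scale carry the usual caveat of a
maximum over noisy cells: with 1000 trials per cell the max over a
plateau of ~25–50 cells sits roughly one to two binomial standard errors
above the plateau's true value.

## Known limitations

* Dense solves only: the state-space cap (10,000 states by default) means
  exact quantities are available for groups up to roughly 100 members
  each; beyond that, the Monte-Carlo engine is the intended path.
* The sweep layer runs cells serially; the per-cell seed derivation is
  scheduler-independent by construction, so a parallel map over cells is
  safe for callers who need it.
* Homophily is a group-level constant; per-agent heterogeneity, more than
  two groups, learning noise and trait innovation are out of scope.
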