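"""Shared domain types for the two-group diffusion model.

The model describes a metapopulation of ``N`` agents split into a minority
group (fraction ``m``) and a majority group.  Each agent carries one of two
behavioural traits — adaptive (``a``, fitness ``f_a``) or non-adaptive
(``A``, fitness ``f_A``) — and relearns its trait every round from a teacher
chosen by homophily-weighted, payoff-biased sampling.  A trial ends when one
trait fixates in the whole metapopulation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Trait",
    "Group",
    "StartCondition",
    "ModelConfig",
    "TrialResult",
    "ConfigError",
    "trial_rng",
]


class ConfigError(ValueError):
    """Raised when a model configuration violates a documented bound."""


class Trait(enum.IntEnum):
    """Behavioural trait: exactly two states exist."""

    NON_ADAPTIVE = 0
    ADAPTIVE = 1


class Group(enum.IntEnum):
    MINORITY = 0
    MAJORITY = 1


class StartCondition(str, enum.Enum):
    """Which group(s) hold the single initial adopter(s)."""

    MINORITY = "minority"
    MAJORITY = "majority"
    BOTH = "both"


def _round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (not banker's)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass(frozen=True)
class ModelConfig:
    """Full parameterisation of one model run.

    Parameters
    ----------
    N : int
        Total metapopulation size.
    m : float
        Minority fraction, in (0, 0.5].  The realised minority size is
        ``round(m * N)`` (ties away from zero) and must be at least 2, as
        must the majority size.
    h_min, h_maj : float
        Group-level homophily in [0, 1].  An agent in a group with
        homophily ``h`` samples its teacher from its own group with
        probability ``(1 + h) / 2``.
    f_a, f_A : float
        Positive trait fitnesses.  Adaptation means ``f_a > f_A``, but
        equal or reversed fitnesses are permitted (neutral-drift checks).
    start_condition : StartCondition
        Where the initial adopter(s) sit: one agent in the minority, one
        in the majority, or one in each.
    max_steps : int
        Hard cap on rounds; a trial still unresolved at the cap is
        reported as censored, never silently truncated.
    seed : int
        Root RNG seed for the trial.
    """

    N: int = 1000
    m: float = 0.05
    h_min: float = 0.0
    h_maj: float = 0.0
    f_a: float = 1.2
    f_A: float = 1.0
    start_condition: StartCondition = StartCondition.MINORITY
    max_steps: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "start_condition", StartCondition(self.start_condition)
        )
        if self.N <= 0:
            raise ConfigError(f"N must be a positive integer, got {self.N}")
        if not (0.0 < self.m <= 0.5):
            raise ConfigError(f"m must lie in (0, 0.5], got {self.m}")
        for name in ("h_min", "h_maj"):
            h = getattr(self, name)
            if not (0.0 <= h <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {h}")
        if self.f_a <= 0 or self.f_A <= 0:
            raise ConfigError(
                f"fitnesses must be positive, got f_a={self.f_a}, f_A={self.f_A}"
            )
        if self.max_steps <= 0:
            raise ConfigError(f"max_steps must be positive, got {self.max_steps}")
        s_min = _round_half_away(self.m * self.N)
        s_maj = self.N - s_min
        if s_min < 2:
            raise ConfigError(
                f"realized minority size s_min={s_min} violates s_min >= 2 "
                f"(m={self.m}, N={self.N})"
            )
        if s_maj < 2:
            raise ConfigError(
                f"realized majority size s_maj={s_maj} violates s_maj >= 2 "
                f"(m={self.m}, N={self.N})"
            )

    @property
    def s_min(self) -> int:
        """Realised minority-group size, ``round(m * N)``."""
        return _round_half_away(self.m * self.N)

    @property
    def s_maj(self) -> int:
        """Realised majority-group size, ``N - s_min``."""
        return self.N - self.s_min

    def group_size(self, group: Group) -> int:
        return self.s_min if group == Group.MINORITY else self.s_maj

    def homophily(self, group: Group) -> float:
        return self.h_min if group == Group.MINORITY else self.h_maj

    def fitness(self, trait: Trait) -> float:
        return self.f_a if trait == Trait.ADAPTIVE else self.f_A

    def replace(self, **kwargs) -> "ModelConfig":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


@dataclass
class TrialResult:
    """Outcome of a single trial.

    ``outcome`` is ``"success"`` when all N agents end adaptive,
    ``"failure"`` when all end non-adaptive, and ``"censored"`` when the
    step cap was hit with the population still polymorphic.  ``series``,
    when recorded, lists ``(step, minority adopters, majority adopters)``
    starting at step 0.
    """

    outcome: str
    steps: int
    series: Optional[list[tuple[int, int, int]]] = field(default=None)

    @property
    def success(self) -> bool:
        return self.outcome == "success"


def trial_rng(root_seed: int, *key: int) -> np.random.Generator:
    """Deterministic child generator for ``(root seed, key...)``.

    Child streams are derived with :class:`numpy.random.SeedSequence`
    spawn keys, so batches are reproducible and order-independent under
    any execution schedule.
    """
    return np.random.default_rng(np.random.SeedSequence(root_seed, spawn_key=key))
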