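"""Seeded trial batches, homophily-grid sweeps, and summary statistics.

Reproduces the study design around the simulator: for each homophily pair
``(h_min, h_maj)`` and start condition, the *success rate* is the fraction
of independent trials ending with the adaptive trait fixated (1000 trials
per cell by default), together with conditional mean rounds to success and
to failure.  Entire sweeps are pure functions of their spec: per-cell and
per-trial RNG streams are derived deterministically from the root seed and
the cell coordinates, so results are independent of execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .agent import run_trial
from .counts import count_trial
from .types import ModelConfig, StartCondition, TrialResult, trial_rng

__all__ = [
    "TABLE1_GRID",
    "SweepSpec",
    "SweepCell",
    "SweepTable",
    "run_batch",
    "run_sweep",
    "summarize_by_start",
    "record_prevalence_series",
]

logger = logging.getLogger("homodiff")

#: the study's homophily grid: 0.0 to 0.95 in steps of 0.05, then 0.99
#: (1.0 is excluded from default sweeps: with a single-group start and both
#: homophilies at 1.0, fixation is impossible)
TABLE1_GRID: tuple[float, ...] = tuple(
    round(0.05 * i, 2) for i in range(20)
) + (0.99,)

_ENGINES = {"agent": run_trial, "count": count_trial}


@dataclass(frozen=True)
class SweepSpec:
    """A full sweep: grid x start conditions x trials, plus seeding."""

    base: ModelConfig = field(default_factory=ModelConfig)
    grid_h_min: tuple[float, ...] = TABLE1_GRID
    grid_h_maj: tuple[float, ...] = TABLE1_GRID
    start_conditions: tuple[StartCondition, ...] = (
        StartCondition.MINORITY,
        StartCondition.MAJORITY,
        StartCondition.BOTH,
    )
    n_trials: int = 1000
    root_seed: int = 0
    engine: str = "count"

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for h in (*self.grid_h_min, *self.grid_h_maj):
            if not (0.0 <= h <= 1.0):
                raise ValueError(f"grid value {h} outside [0, 1]")
        if self.engine not in _ENGINES:
            raise ValueError(f"engine must be one of {sorted(_ENGINES)}")
        object.__setattr__(
            self,
            "start_conditions",
            tuple(StartCondition(s) for s in self.start_conditions),
        )


@dataclass
class SweepCell:
    """Aggregated outcomes of one (h_min, h_maj, start) grid point."""

    h_min: float
    h_maj: float
    start_condition: StartCondition
    n_trials: int
    n_success: int
    n_failure: int
    n_censored: int
    success_rate: float
    mean_steps_success: Optional[float]
    mean_steps_failure: Optional[float]
    mean_steps: float

    def __post_init__(self) -> None:
        assert self.n_success + self.n_failure + self.n_censored == self.n_trials


@dataclass
class SweepTable:
    """Cells of a completed sweep plus run provenance."""

    cells: list[SweepCell]
    provenance: dict

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(c) for c in self.cells])
        df["start_condition"] = df["start_condition"].map(
            lambda s: StartCondition(s).value
        )
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    def to_json(self, path) -> None:
        import json

        payload = {
            "provenance": self.provenance,
            "cells": self.to_dataframe().to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _aggregate(
    results: Iterable[TrialResult],
    h_min: float,
    h_maj: float,
    start: StartCondition,
) -> SweepCell:
    succ_steps: list[int] = []
    fail_steps: list[int] = []
    n_cens = 0
    all_steps: list[int] = []
    for r in results:
        all_steps.append(r.steps)
        if r.outcome == "success":
            succ_steps.append(r.steps)
        elif r.outcome == "failure":
            fail_steps.append(r.steps)
        else:
            n_cens += 1
    n_trials = len(all_steps)
    cell = SweepCell(
        h_min=h_min,
        h_maj=h_maj,
        start_condition=start,
        n_trials=n_trials,
        n_success=len(succ_steps),
        n_failure=len(fail_steps),
        n_censored=n_cens,
        success_rate=len(succ_steps) / n_trials,
        mean_steps_success=float(np.mean(succ_steps)) if succ_steps else None,
        mean_steps_failure=float(np.mean(fail_steps)) if fail_steps else None,
        mean_steps=float(np.mean(all_steps)),
    )
    if n_cens:
        logger.warning(
            "cell (h_min=%s, h_maj=%s, start=%s): %d of %d trials censored "
            "at the step cap; censored trials are excluded from success_rate "
            "and step statistics",
            h_min, h_maj, start.value, n_cens, n_trials,
        )
    return cell


def run_batch(
    config: ModelConfig,
    n_trials: int,
    root_seed: int,
    engine: str = "count",
    start=None,
    _cell_key: tuple[int, ...] = (),
) -> SweepCell:
    """Run ``n_trials`` independent trials; trial k uses the child stream
    derived from ``(root_seed, *cell key, k)``.

    Identical inputs yield an identical cell regardless of execution order.
    ``start`` (count engine only) overrides the initial adopter counts.
    """
    trial_fn = _ENGINES[engine]
    kwargs = {} if start is None else {"start": start}
    results = (
        trial_fn(config, trial_rng(root_seed, *_cell_key, k), **kwargs)
        for k in range(n_trials)
    )
    return _aggregate(results, config.h_min, config.h_maj, config.start_condition)


def run_sweep(spec: SweepSpec) -> SweepTable:
    """One cell per (start condition, h_min, h_maj) grid point."""
    cells: list[SweepCell] = []
    for si, start in enumerate(spec.start_conditions):
        for i, h_min in enumerate(spec.grid_h_min):
            for j, h_maj in enumerate(spec.grid_h_maj):
                config = spec.base.replace(
                    h_min=h_min, h_maj=h_maj, start_condition=start
                )
                cells.append(
                    run_batch(
                        config,
                        spec.n_trials,
                        spec.root_seed,
                        engine=spec.engine,
                        _cell_key=(si, i, j),
                    )
                )
    provenance = {
        "root_seed": spec.root_seed,
        "engine": spec.engine,
        "n_trials": spec.n_trials,
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    return SweepTable(cells=cells, provenance=provenance)


def summarize_by_start(table: SweepTable) -> pd.DataFrame:
    """Per-start-condition summary of cell success rates and step means.

    One row per start condition: the mean and full multiset of cell
    success rates, means of the conditional step statistics over cells
    where they are defined, and the argmax cell.
    """
    df = table.to_dataframe()
    if df.empty:
        raise ValueError("empty sweep table")
    rows = []
    for start, grp in df.groupby("start_condition", sort=False):
        best = grp.loc[grp["success_rate"].idxmax()]
        rows.append(
            {
                "start_condition": start,
                "n_cells": len(grp),
                "mean_success_rate": grp["success_rate"].mean(),
                "success_rates": grp["success_rate"].tolist(),
                "mean_steps_success": grp["mean_steps_success"].dropna().mean(),
                "mean_steps_failure": grp["mean_steps_failure"].dropna().mean(),
                "max_success_rate": best["success_rate"],
                "argmax_h_min": best["h_min"],
                "argmax_h_maj": best["h_maj"],
            }
        )
    return pd.DataFrame(rows).set_index("start_condition")


def record_prevalence_series(
    config: ModelConfig,
    n_trials: int,
    root_seed: int,
    engine: str = "count",
) -> pd.DataFrame:
    """Per-trial trajectories of adopter fraction per group.

    Long-format frame with columns ``trial, step, group, prevalence``
    (group in {"minority", "majority"}), e.g. ten trials at
    h_min = h_maj = 0.75 or 0.99 to reproduce the study's time-series
    panels.
    """
    trial_fn = _ENGINES[engine]
    rows = []
    for k in range(n_trials):
        result = trial_fn(config, trial_rng(root_seed, k), record_series=True)
        for step, n_min, n_maj in result.series:
            rows.append((k, step, "minority", n_min / config.s_min))
            rows.append((k, step, "majority", n_maj / config.s_maj))
    return pd.DataFrame(rows, columns=["trial", "step", "group", "prevalence"])
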