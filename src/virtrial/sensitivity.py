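"""Stimulus sensitivity analysis.

Two designs probe how the disease tSignal depends on the drug's target set:

* a one-at-a-time sweep scaling each target's intensity over
  {0, 25, 50, 75, 100}% of the drug's effect while holding the others fixed
  (the finite-difference realization of d(tSignal)/d(Xi)); and
* a robustness curve extending the target set with j = 1..20 random
  non-target proteins (50 independent extension sets per j) to measure how
  diluting the stimulus with random targets degrades the response.

Both report percentages of the unmodified model's mean tSignal (100% = the
original stimulus), averaged over a random 5% subsample of the trained
solution pool, mirroring the study's use of 1,250 of 25,000 solutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .definitions import DiseaseDefinition, Network
from .moa import tsignal
from .qsp import MathematicalSolution, default_steps, propagate

DEFAULT_LEVELS = (0.0, 0.25, 0.5, 0.75, 1.0)


class SensitivityError(ValueError):
    pass


def subsample_size(pool_size: int, fraction: float) -> int:
    """Round-half-up of fraction * pool_size, floored at 1."""
    return max(1, int(np.floor(fraction * pool_size + 0.5)))


def subsample_solutions(
    pool: list[MathematicalSolution], fraction: float = 0.05, seed: int = 0
) -> list[MathematicalSolution]:
    """Uniform without-replacement subsample of the solution pool.

    The subsample size is round(fraction * |pool|) with a floor of 1
    (25,000 solutions at 5% -> 1,250). Deterministic per seed.
    """
    if not pool:
        raise SensitivityError("empty solution pool")
    if not 0.0 < fraction <= 1.0:
        raise SensitivityError("fraction must be in (0,1]")
    k = subsample_size(len(pool), fraction)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in sorted(idx)]


def _mean_tsignal(
    solutions, network, disease, stimulus, steps
) -> float:
    vals = [
        tsignal(propagate(sol, network, stimulus, steps), disease).value
        for sol in solutions
    ]
    return float(np.mean(vals))


@dataclass
class SweepResult:
    """Tidy per-target x per-level percent-of-reference tSignal table."""

    table: pd.DataFrame  # target, level, percent
    reference_tsignal: float

    def percent(self, target: str, level: float) -> float:
        row = self.table[
            (self.table["target"] == target) & (self.table["level"] == level)
        ]
        return float(row["percent"].iloc[0])


def single_target_sweep(
    solutions: list[MathematicalSolution],
    network: Network,
    disease: DiseaseDefinition,
    drug_stimulus: dict[str, float],
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    steps: int | None = None,
) -> SweepResult:
    """One-at-a-time intensity sweep over the drug's targets.

    For each target and each level, only that target's intensity is scaled
    by the level; the solution-averaged tSignal is reported as a percentage
    of the unmodified model's (level 1 is exactly 100% for every target).
    """
    if not solutions:
        raise SensitivityError("no solutions provided")
    if not drug_stimulus:
        raise SensitivityError("empty drug stimulus")
    if steps is None:
        steps = default_steps(network)
    ref = _mean_tsignal(solutions, network, disease, drug_stimulus, steps)
    if ref == 0.0:
        raise SensitivityError("reference tSignal is 0; percentage undefined")
    rows = []
    for target in drug_stimulus:
        for level in levels:
            stim = dict(drug_stimulus)
            stim[target] = drug_stimulus[target] * level
            val = _mean_tsignal(solutions, network, disease, stim, steps)
            rows.append((target, level, 100.0 * val / ref))
    return SweepResult(
        pd.DataFrame(rows, columns=["target", "level", "percent"]), ref
    )


@dataclass
class RobustnessCurve:
    """Percent-of-reference tSignal per addition count j = 0..max_added."""

    table: pd.DataFrame  # n_added, set_index, percent
    reference_tsignal: float

    def mean_percent(self, n_added: int) -> float:
        if n_added == 0:
            return 100.0
        sel = self.table[self.table["n_added"] == n_added]
        return float(sel["percent"].mean())


def extended_set_robustness(
    solutions: list[MathematicalSolution],
    network: Network,
    disease: DiseaseDefinition,
    drug_stimulus: dict[str, float],
    n_sets: int = 50,
    max_added: int = 20,
    added_intensity: float = 1.0,
    seed: int = 0,
    steps: int | None = None,
) -> RobustnessCurve:
    """Random target-set extension robustness analysis.

    For every addition count j = 1..max_added, draws ``n_sets`` fresh random
    extensions of j non-target proteins (uniform over the network, random
    +/-1 effects at ``added_intensity``), propagates, and records the
    percent-of-reference tSignal; j = 0 is 100% by definition.
    """
    if not solutions:
        raise SensitivityError("no solutions provided")
    non_targets = [n for n in network.nodes if n not in drug_stimulus]
    if max_added > len(non_targets):
        raise SensitivityError("max_added exceeds available non-target nodes")
    if steps is None:
        steps = default_steps(network)
    ref = _mean_tsignal(solutions, network, disease, drug_stimulus, steps)
    if ref == 0.0:
        raise SensitivityError("reference tSignal is 0; percentage undefined")
    rng = np.random.default_rng(seed)
    rows = [(0, 0, 100.0)]
    for j in range(1, max_added + 1):
        for k in range(n_sets):
            added = rng.choice(non_targets, size=j, replace=False)
            effects = rng.choice([-1.0, 1.0], size=j)
            stim = dict(drug_stimulus)
            for g, e in zip(added, effects):
                stim[str(g)] = float(e * added_intensity)
            val = _mean_tsignal(solutions, network, disease, stim, steps)
            rows.append((j, k, 100.0 * val / ref))
    return RobustnessCurve(
        pd.DataFrame(rows, columns=["n_added", "set_index", "percent"]), ref
    )
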