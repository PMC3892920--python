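"""Branching-process oracle and synthetic-cohort generator.

The closed form in :mod:`preresist.model` approximates an explicit
birth-death-mutation branching process.  This module simulates that process
exactly on its embedded jump chain: each event is a birth with probability
l/(l+d) (otherwise a death) of a uniformly chosen cell; each division of a
sensitive cell turns one daughter resistant with probability u, and each
division of a resistant cell turns one daughter doubly resistant with
probability u2.  Only the jump chain matters for questions indexed by
population size, so no clock is simulated.

Runs start from a single sensitive cell and stop when the population reaches
``target_size``.  A lineage that goes extinct is restarted (counted), i.e.
results are conditioned on non-extinction — the observed tumor did reach
detection size.

Also provides a synthetic patient cohort emulating a trial-like diameter
distribution (truncated log-normal with ~75% of tumors above 7 cm).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "SimulationConfig",
    "TrajectoryResult",
    "MonteCarloEstimate",
    "CohortSpec",
    "ExtinctionError",
    "simulate_to_size",
    "estimate_resistance_probability",
    "exact_no_mutant_probability_pure_birth",
    "generate_cohort",
]


class ExtinctionError(RuntimeError):
    """Raised when every allowed restart went extinct before reaching target."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one branching-process run.

    u2 = 0 disables the second-mutation channel.  ``seed`` makes the run
    fully reproducible; ``max_restarts`` caps extinction restarts (each
    lineage starting from one cell dies out with probability d/l).
    """

    l: float = 1.0
    d: float = 0.0
    u: float = 1e-8
    u2: float = 0.0
    target_size: int = 1000
    seed: int = 0
    max_restarts: int = 10_000

    def __post_init__(self) -> None:
        if not self.l > self.d >= 0.0:
            raise ValueError(f"require l > d >= 0, got l={self.l}, d={self.d}")
        if not (0.0 <= self.u < 1.0 and 0.0 <= self.u2 < 1.0):
            raise ValueError(f"mutation probabilities must lie in [0, 1), got u={self.u}, u2={self.u2}")
        if self.target_size < 1:
            raise ValueError(f"target_size must be >= 1, got {self.target_size}")
        if self.max_restarts < 1:
            raise ValueError(f"max_restarts must be >= 1, got {self.max_restarts}")


@dataclass(frozen=True)
class TrajectoryResult:
    """Final state of one run conditioned on reaching the target size."""

    reached_target: bool
    final_sensitive: int
    final_resistant: int
    final_double_resistant: int
    n_divisions: int
    n_mutation_events: int
    n_restarts: int


@dataclass(frozen=True)
class MonteCarloEstimate:
    """Summary over repeated runs: p_hat with a 95% Wilson score interval."""

    n_reps: int
    n_positive: int
    p_hat: float
    ci_low: float
    ci_high: float
    mean_resistant_fraction: float
    sd_resistant_fraction: float

    def to_dict(self) -> dict:
        return asdict(self)


@njit(cache=False)
def _simulate_core(l, d, u, u2, target_size, seed, max_restarts):
    """Embedded-jump-chain simulation; returns the TrajectoryResult tuple."""
    np.random.seed(seed)
    p_birth = l / (l + d)
    n_restarts = 0
    while True:
        n_sens = 1
        n_res = 0
        n_dbl = 0
        total = 1
        n_div = 0
        n_mut = 0
        while 0 < total < target_size:
            if d > 0.0 and np.random.random() >= p_birth:
                # death of a uniformly chosen cell
                r = np.random.random() * total
                if r < n_sens:
                    n_sens -= 1
                elif r < n_sens + n_res:
                    n_res -= 1
                else:
                    n_dbl -= 1
                total -= 1
            else:
                # division of a uniformly chosen cell; at most one daughter mutates
                n_div += 1
                r = np.random.random() * total
                if r < n_sens:
                    if u > 0.0 and np.random.random() < u:
                        n_res += 1
                        n_mut += 1
                    else:
                        n_sens += 1
                elif r < n_sens + n_res:
                    if u2 > 0.0 and np.random.random() < u2:
                        n_dbl += 1
                        n_mut += 1
                    else:
                        n_res += 1
                else:
                    n_dbl += 1
                total += 1
        if total == target_size:
            return True, n_sens, n_res, n_dbl, n_div, n_mut, n_restarts
        n_restarts += 1
        if n_restarts >= max_restarts:
            return False, 0, 0, 0, n_div, n_mut, n_restarts


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Independent per-replicate uint32 seeds (< 2^31) from one root seed."""
    return (np.random.SeedSequence(seed).generate_state(n) % np.uint32(2**31)).astype(np.uint32)


def simulate_to_size(config: SimulationConfig) -> TrajectoryResult:
    """Run the branching process from one sensitive cell to ``target_size``.

    Restarts (with a fresh segment of the seeded RNG stream) if the lineage
    goes extinct; raises :class:`ExtinctionError` after ``max_restarts``.
    """
    seed = int(_spawn_seeds(config.seed, 1)[0])
    reached, n_sens, n_res, n_dbl, n_div, n_mut, n_restarts = _simulate_core(
        config.l, config.d, config.u, config.u2,
        config.target_size, seed, config.max_restarts,
    )
    if not reached:
        raise ExtinctionError(
            f"all {config.max_restarts} restarts went extinct before reaching "
            f"{config.target_size} cells (per-lineage extinction probability d/l = {config.d / config.l:.4g})"
        )
    return TrajectoryResult(
        reached_target=True,
        final_sensitive=int(n_sens),
        final_resistant=int(n_res),
        final_double_resistant=int(n_dbl),
        n_divisions=int(n_div),
        n_mutation_events=int(n_mut),
        n_restarts=int(n_restarts),
    )


def estimate_resistance_probability(config: SimulationConfig, n_reps: int) -> MonteCarloEstimate:
    """Monte-Carlo estimate of P(>= 1 resistant cell at target size).

    Runs ``n_reps`` independent trajectories (replicate seeds spawned from
    ``config.seed``, so the result does not depend on execution order) and
    summarizes the positive fraction with a 95% Wilson score interval.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    seeds = _spawn_seeds(config.seed, n_reps)
    n_positive = 0
    fractions = np.empty(n_reps)
    for i in range(n_reps):
        reached, _, n_res, n_dbl, n_div, _, _ = _simulate_core(
            config.l, config.d, config.u, config.u2,
            config.target_size, int(seeds[i]), config.max_restarts,
        )
        if not reached:
            raise ExtinctionError(
                f"replicate {i} exhausted {config.max_restarts} extinction restarts "
                f"(extinction probability d/l = {config.d / config.l:.4g})"
            )
        n_mutant = n_res + n_dbl
        if n_mutant > 0:
            n_positive += 1
        fractions[i] = n_mutant / config.target_size
    ci_low, ci_high = proportion_confint(n_positive, n_reps, alpha=0.05, method="wilson")
    return MonteCarloEstimate(
        n_reps=n_reps,
        n_positive=n_positive,
        p_hat=n_positive / n_reps,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        mean_resistant_fraction=float(fractions.mean()),
        sd_resistant_fraction=float(fractions.std(ddof=1)) if n_reps > 1 else 0.0,
    )


def exact_no_mutant_probability_pure_birth(u: float, M: int) -> float:
    """Exact P(>= 1 mutant at size M) under pure birth: 1 - (1-u)^(M-1).

    With d = 0 growth from 1 to M cells takes exactly M - 1 divisions, each
    producing a mutant daughter independently with probability u, and no
    mutant lineage ever dies — an independent combinatorial oracle for the
    d = 0 regime.
    """
    if M < 1:
        raise ValueError(f"M must be >= 1, got {M}")
    if not 0.0 <= u < 1.0:
        raise ValueError(f"u must lie in [0, 1), got {u}")
    return -np.expm1((M - 1) * np.log1p(-u))


@dataclass(frozen=True)
class CohortSpec:
    """Truncated log-normal diameter distribution for a synthetic cohort.

    The defaults place about 75% of the mass above 7 cm, emulating the size
    distribution reported for advanced-GIST trial populations, with support
    on [1, 40] cm.
    """

    n_patients: int = 147
    log_mean: float = 2.351
    log_sd: float = 0.6
    d_min: float = 1.0
    d_max: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError(f"n_patients must be >= 0, got {self.n_patients}")
        if not self.log_sd > 0.0:
            raise ValueError(f"log_sd must be positive, got {self.log_sd}")
        if not 0.0 < self.d_min < self.d_max:
            raise ValueError(f"require 0 < d_min < d_max, got [{self.d_min}, {self.d_max}]")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Synthetic patient table with columns ``patient_id, diameter_cm``."""
    rng = np.random.default_rng(spec.seed)
    a = (np.log(spec.d_min) - spec.log_mean) / spec.log_sd
    b = (np.log(spec.d_max) - spec.log_mean) / spec.log_sd
    log_d = stats.truncnorm.rvs(a, b, loc=spec.log_mean, scale=spec.log_sd,
                                size=spec.n_patients, random_state=rng)
    return pd.DataFrame({
        "patient_id": [f"P{i + 1:04d}" for i in range(spec.n_patients)],
        "diameter_cm": np.exp(log_d),
    })
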