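"""Moth-flame optimization (MFO) over a bounded continuous search space.

MFO is a population metaheuristic in which candidate solutions ("moths") fly
on logarithmic spirals around the best solutions found so far ("flames").
Each iteration the moths are re-evaluated, the flame set is rebuilt from the
pooled best records (elitism), and the number of flames shrinks linearly to
one so that late iterations concentrate the search around the incumbent best.

The implementation is deliberately self-contained and fully seeded: two runs
with the same configuration and objective produce bit-identical traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .exceptions import ConfigurationError

__all__ = [
    "MFOConfig",
    "MothPopulation",
    "FlameSet",
    "OptimizationResult",
    "round_half_away",
    "flame_count",
    "init_population",
    "spiral_update",
    "update_flames",
    "run_mfo",
]


@dataclass
class MFOConfig:
    """Settings for one optimization run.

    ``bounds`` is a sequence of ``(lower, upper)`` pairs, one per search
    dimension; every moth coordinate stays inside its pair at all times.
    """

    bounds: Sequence[tuple[float, float]]
    n_moths: int = 20
    max_iter: int = 30
    spiral_b: float = 1.0
    seed: int = 0
    signed_distance: bool = False

    def __post_init__(self) -> None:
        if self.n_moths < 1:
            raise ConfigurationError("n_moths must be >= 1")
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be >= 1")
        lo, hi = self.bounds_arrays()
        if lo.shape != hi.shape or lo.ndim != 1 or lo.size == 0:
            raise ConfigurationError("bounds must be a non-empty list of (low, high) pairs")
        bad = np.nonzero(~(lo < hi))[0]
        if bad.size:
            raise ConfigurationError(
                f"invalid bounds at dimension(s) {bad.tolist()}: lower must be < upper"
            )

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        arr = np.asarray(self.bounds, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ConfigurationError("bounds must be pairs of (low, high)")
        return arr[:, 0].copy(), arr[:, 1].copy()

    @property
    def n_dim(self) -> int:
        return len(self.bounds)


@dataclass
class MothPopulation:
    """Current search agents: positions and their objective values."""

    positions: np.ndarray  # (n, d)
    fitness: np.ndarray  # (n,), lower is better; NaN before evaluation


@dataclass
class FlameSet:
    """Best-so-far records, sorted by ascending fitness."""

    positions: np.ndarray  # (k, d)
    fitness: np.ndarray  # (k,), non-decreasing


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    trace: "object" = field(default=None)  # pandas.DataFrame


def round_half_away(x: float | np.ndarray) -> np.ndarray:
    """Round halves away from zero (2.5 -> 3, -2.5 -> -3).

    ``np.round`` uses banker's rounding, which would make the flame-count
    schedule depend on parity; half-away-from-zero keeps it monotone.
    """
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def flame_count(t: int, max_iter: int, n_max: int) -> int:
    """Adaptive flame number at iteration ``t`` (1-based).

    Follows round(N - t*(N-1)/T), clamped to at least one flame, so the
    retained best set shrinks linearly from N to a single flame at t = T.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if not 1 <= t <= max_iter:
        raise ValueError(f"iteration t={t} outside 1..{max_iter}")
    count = int(round_half_away(n_max - t * (n_max - 1) / max_iter))
    return max(count, 1)


def init_population(config: MFOConfig, rng: np.random.Generator | None = None) -> MothPopulation:
    """Draw the initial moth positions uniformly inside the bounds."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds_arrays()
    positions = rng.uniform(lo, hi, size=(config.n_moths, config.n_dim))
    fitness = np.full(config.n_moths, np.nan)
    return MothPopulation(positions=positions, fitness=fitness)


def spiral_update(
    moth: np.ndarray,
    flame: np.ndarray,
    b: float,
    t: float | np.ndarray,
    signed_distance: bool = False,
) -> np.ndarray:
    """One logarithmic-spiral step of a moth around a flame.

    Returns ``D * exp(b t) * cos(2 pi t) + F`` coordinate-wise, where D is
    the coordinate-wise distance between moth and flame.  By default D is the
    absolute distance |M - F| (the canonical spiral, symmetric around the
    flame); ``signed_distance=True`` uses the signed difference M - F instead.
    ``t`` may be a scalar or a per-coordinate array in [-1, 1].
    """
    moth = np.asarray(moth, dtype=float)
    flame = np.asarray(flame, dtype=float)
    if moth.shape != flame.shape:
        raise ValueError(f"dimension mismatch: moth {moth.shape} vs flame {flame.shape}")
    dist = (moth - flame) if signed_distance else np.abs(moth - flame)
    t = np.asarray(t, dtype=float)
    return dist * np.exp(b * t) * np.cos(2.0 * math.pi * t) + flame


def update_flames(
    moths: MothPopulation, previous: FlameSet | None, flame_no: int
) -> FlameSet:
    """Rebuild the flame set from the pooled moth and flame records.

    Takes the ``flame_no`` best records by fitness from the union of the
    current moths and the previous flames, sorted ascending.  Pooling makes
    the rule elitist: the global best can never be lost.
    """
    if flame_no < 1:
        raise ValueError("flame_no must be >= 1")
    if previous is None or previous.positions.size == 0:
        pool_pos = moths.positions
        pool_fit = moths.fitness
    else:
        pool_pos = np.vstack([moths.positions, previous.positions])
        pool_fit = np.concatenate([moths.fitness, previous.fitness])
    order = np.argsort(pool_fit, kind="stable")[: min(flame_no, pool_fit.size)]
    return FlameSet(positions=pool_pos[order].copy(), fitness=pool_fit[order].copy())


def _evaluate(objective: Callable[[np.ndarray], float], positions: np.ndarray) -> np.ndarray:
    """Evaluate the objective row-wise; non-finite values become +inf."""
    out = np.empty(positions.shape[0])
    for i, pos in enumerate(positions):
        try:
            val = float(objective(pos))
        except (FloatingPointError, OverflowError, ZeroDivisionError):
            val = np.inf
        out[i] = val if np.isfinite(val) else np.inf
    return out


def run_mfo(
    objective: Callable[[np.ndarray], float],
    config: MFOConfig,
    callback: Callable[[int, FlameSet], None] | None = None,
) -> OptimizationResult:
    """Run the full moth-flame loop and return the best record plus a trace.

    Per iteration: evaluate all moths, merge them into the flame set, shrink
    the flame count, then spiral-move every moth toward its paired flame
    (moth i pairs with flame i; moths beyond the flame count pair with the
    last kept flame) and clip the result to the bounds.

    The trace is a DataFrame with one row per iteration: ``iteration``,
    ``flame_count``, ``best_fitness``, ``mean_fitness`` and the best position
    coordinates; ``best_fitness`` is non-increasing by construction.
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds_arrays()
    moths = init_population(config, rng)
    flames: FlameSet | None = None
    records = []

    for t in range(1, config.max_iter + 1):
        moths.fitness = _evaluate(objective, moths.positions)
        n_flames = flame_count(t, config.max_iter, config.n_moths)
        flames = update_flames(moths, flames, n_flames)
        if callback is not None:
            callback(t, flames)
        finite = moths.fitness[np.isfinite(moths.fitness)]
        records.append(
            {
                "iteration": t,
                "flame_count": n_flames,
                "best_fitness": float(flames.fitness[0]),
                "mean_fitness": float(finite.mean()) if finite.size else np.inf,
                **{f"best_x{j}": float(v) for j, v in enumerate(flames.positions[0])},
            }
        )
        # Spiral move (skipped after the last evaluation round).
        if t == config.max_iter:
            break
        pair = np.minimum(np.arange(config.n_moths), n_flames - 1)
        tau = rng.uniform(-1.0, 1.0, size=moths.positions.shape)
        new_pos = spiral_update(
            moths.positions,
            flames.positions[pair],
            config.spiral_b,
            tau,
            signed_distance=config.signed_distance,
        )
        moths.positions = np.clip(new_pos, lo, hi)

    trace = pd.DataFrame.from_records(records)
    assert flames is not None
    return OptimizationResult(
        best_position=flames.positions[0].copy(),
        best_fitness=float(flames.fitness[0]),
        trace=trace,
    )
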