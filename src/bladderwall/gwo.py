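"""Grey Wolf Optimizer for bound-constrained continuous optimization.

A pack of candidate solutions moves under the guidance of its three best
members (alpha, beta, delta).  For each wolf X and leader L:

    D_L = |C * X_L - X|,   candidate = X_L - A * D_L
    A = 2 a r1 - a,        C = 2 r2

with r1, r2 fresh uniform draws per wolf, per leader, per dimension, and
the control scalar ``a`` decreasing linearly from 2 to 0 over the run.
The new position is the absolute value of the mean of the three
candidates (``strict_update=True``, the form used by the bladder-wall
tuning; positions here are positive log-hyperparameters, so the absolute
value is harmless); ``strict_update=False`` restores the canonical
unsigned mean.  Positions are clipped to the search box after each move.

In the pipeline the optimizer tunes the SVM hyperparameters (C, gamma) by
maximizing cross-validated accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GWOConfig", "WolfPack", "GWOResult", "update_positions", "optimize"]


@dataclass(frozen=True)
class GWOConfig:
    pack_size: int = 10
    iterations: int = 30
    bounds: tuple[tuple[float, float], ...] = ((-2.0, 2.0), (-4.0, 1.0))
    seed: int = 0
    mode: str = "maximize"          # or "minimize"
    strict_update: bool = True      # |mean| of leaders, as printed

    def __post_init__(self) -> None:
        if self.pack_size < 3:
            raise ValueError("pack_size must be >= 3 (alpha, beta, delta must exist)")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"invalid bound ({lo}, {hi}): low must be < high")
        if self.mode not in ("maximize", "minimize"):
            raise ValueError(f"mode must be 'maximize' or 'minimize', got {self.mode!r}")


@dataclass
class WolfPack:
    positions: np.ndarray            # (pack_size, dim)
    fitnesses: np.ndarray            # (pack_size,) in maximize orientation
    leaders: np.ndarray              # (3, dim): alpha, beta, delta


@dataclass
class GWOResult:
    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray = field(default_factory=lambda: np.empty(0))


def _rank_leaders(positions: np.ndarray, fitnesses: np.ndarray) -> np.ndarray:
    order = np.argsort(-fitnesses, kind="stable")
    return positions[order[:3]].copy()


def update_positions(
    pack: WolfPack,
    a: float,
    rng: np.random.Generator,
    bounds: np.ndarray,
    strict_update: bool = True,
) -> np.ndarray:
    """One position update of the whole pack; returns the new positions."""
    if not (0.0 <= a <= 2.0):
        raise ValueError(f"control parameter a must be in [0, 2], got {a}")
    n, dim = pack.positions.shape
    new = np.empty_like(pack.positions)
    for w in range(n):
        x = pack.positions[w]
        candidates = np.empty((3, dim))
        for li in range(3):
            xl = pack.leaders[li]
            r1 = rng.uniform(size=dim)
            r2 = rng.uniform(size=dim)
            big_a = 2.0 * a * r1 - a
            big_c = 2.0 * r2
            d = np.abs(big_c * xl - x)
            candidates[li] = xl - big_a * d
        mean = candidates.mean(axis=0)
        new[w] = np.abs(mean) if strict_update else mean
    return np.clip(new, bounds[:, 0], bounds[:, 1])


def optimize(fitness, config: GWOConfig = GWOConfig()) -> GWOResult:
    """Run the optimizer; bit-identical for a fixed ``config.seed``.

    ``fitness`` maps a position vector to a scalar; non-finite values are
    treated as worst-possible.  The returned trace is the best-so-far
    fitness per iteration (non-decreasing in maximize orientation).
    """
    rng = np.random.default_rng(config.seed)
    bounds = np.asarray(config.bounds, dtype=float)
    dim = len(bounds)
    sign = 1.0 if config.mode == "maximize" else -1.0

    def score(x: np.ndarray) -> float:
        v = float(fitness(x))
        if not np.isfinite(v):
            return -np.inf
        return sign * v

    positions = rng.uniform(bounds[:, 0], bounds[:, 1], size=(config.pack_size, dim))
    fitnesses = np.array([score(x) for x in positions])
    pack = WolfPack(positions, fitnesses, _rank_leaders(positions, fitnesses))

    best_i = int(np.argmax(fitnesses))
    best_pos = positions[best_i].copy()
    best_fit = float(fitnesses[best_i])
    trace = []

    for t in range(1, config.iterations + 1):
        a = 2.0 * (1.0 - t / config.iterations)
        new_pos = update_positions(pack, a, rng, bounds, config.strict_update)
        new_fit = np.array([score(x) for x in new_pos])
        pack = WolfPack(new_pos, new_fit, _rank_leaders(new_pos, new_fit))
        i = int(np.argmax(new_fit))
        if new_fit[i] > best_fit:
            best_fit = float(new_fit[i])
            best_pos = new_pos[i].copy()
        trace.append(sign * best_fit)

    return GWOResult(best_position=best_pos, best_fitness=sign * best_fit,
                     trace=np.asarray(trace))
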