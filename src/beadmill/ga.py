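"""Real-coded genetic algorithm over box bounds.

Minimization is the native convention (maximization problems are posed by
negating the objective, the usual sign-flip trick).  The algorithm uses
linear rank-based selection, intermediate blend crossover, Gaussian mutation
scaled to each variable's range and clipped to the bounds, and elitism, all
driven by a single seeded generator so runs are bit-reproducible.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .ann import forward
from .design import Factor
from .rsm import PolynomialModel, RsmFit

__all__ = [
    "GaConfig",
    "GaResult",
    "ga_minimize",
    "optimize_surrogate",
    "surrogate_function",
]


@dataclass(frozen=True)
class GaConfig:
    population_size: int = 50
    generations: int = 100
    crossover_fraction: float = 0.8
    mutation_scale: float = 0.1  # std dev of the Gaussian kick, as a fraction of range
    elite_count: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.crossover_fraction <= 1.0:
            raise ValueError("crossover_fraction must lie in [0, 1]")
        if not 0 <= self.elite_count < self.population_size:
            raise ValueError("need 0 <= elite_count < population_size")
        if self.generations < 1 or self.population_size < 2:
            raise ValueError("population_size >= 2 and generations >= 1 required")


@dataclass
class GaResult:
    best_point: np.ndarray
    best_fitness: float  # minimized objective value
    history_best: list[float] = field(default_factory=list)
    history_mean: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "best_point": self.best_point.tolist(),
            "best_fitness": self.best_fitness,
            "history_best": self.history_best,
            "history_mean": self.history_mean,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def history_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "generation": np.arange(1, len(self.history_best) + 1),
                "best": self.history_best,
                "mean": self.history_mean,
            }
        )


def _evaluate(objective: Callable, pop: np.ndarray) -> np.ndarray:
    vals = np.empty(pop.shape[0])
    for i, x in enumerate(pop):
        v = float(objective(x))
        if not math.isfinite(v):
            raise ValueError(f"objective returned non-finite value {v} at {x.tolist()}")
        vals[i] = v
    return vals


def ga_minimize(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    config: GaConfig = GaConfig(),
) -> GaResult:
    """Minimize a scalar objective over a box with a real-coded GA.

    Rank selection assigns parent probabilities linearly decreasing with
    fitness rank (ties broken by evaluation order via stable sort).  Each
    non-elite child is produced by intermediate crossover of two parents with
    probability ``crossover_fraction``, otherwise by Gaussian mutation of a
    single parent; children are clipped to the bounds.
    """
    bounds_arr = np.asarray([(float(lo), float(hi)) for lo, hi in bounds])
    lo, hi = bounds_arr[:, 0], bounds_arr[:, 1]
    if np.any(lo > hi):
        raise ValueError("each bound must satisfy low <= high")
    span = hi - lo
    d = len(bounds_arr)
    rng = np.random.default_rng(config.seed)

    pop = lo + rng.uniform(size=(config.population_size, d)) * span
    fitness = _evaluate(objective, pop)
    result = GaResult(best_point=pop[np.argmin(fitness)].copy(),
                      best_fitness=float(fitness.min()))

    n = config.population_size
    # linear ranking: best rank gets weight n, worst gets 1
    rank_weights = np.arange(n, 0, -1, dtype=float)
    rank_weights /= rank_weights.sum()

    for _ in range(config.generations):
        order = np.argsort(fitness, kind="stable")
        pop = pop[order]
        fitness = fitness[order]

        children = np.empty_like(pop)
        n_elite = config.elite_count
        children[:n_elite] = pop[:n_elite]
        n_rest = n - n_elite
        do_cross = rng.uniform(size=n_rest) < config.crossover_fraction
        parent_idx = rng.choice(n, size=(n_rest, 2), p=rank_weights)
        u = rng.uniform(size=(n_rest, d))
        noise = rng.normal(0.0, 1.0, size=(n_rest, d)) * (config.mutation_scale * span)
        for i in range(n_rest):
            p1, p2 = pop[parent_idx[i, 0]], pop[parent_idx[i, 1]]
            if do_cross[i]:
                child = p1 + u[i] * (p2 - p1)
            else:
                child = p1 + noise[i]
            children[n_elite + i] = np.clip(child, lo, hi)

        pop = children
        fitness[:n_elite] = fitness[:n_elite]  # elites keep cached fitness
        fitness[n_elite:] = _evaluate(objective, pop[n_elite:])

        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < result.best_fitness:
            result.best_fitness = float(fitness[gen_best])
            result.best_point = pop[gen_best].copy()
        result.history_best.append(float(fitness.min()))
        result.history_mean.append(float(fitness.mean()))

    return result


def surrogate_function(
    surrogate,
    factors: Sequence[Factor] | None = None,
) -> Callable[[np.ndarray], float]:
    """Wrap a trained surrogate as a scalar function of actual-unit inputs.

    Accepts either a polynomial surrogate (:class:`RsmFit` or
    :class:`PolynomialModel`, requiring ``factors`` for the coding transform)
    or a tuple ``(NetworkParameters, (input Normalizer, target Normalizer))``.
    """
    if isinstance(surrogate, (RsmFit, PolynomialModel)):
        model = surrogate.model if isinstance(surrogate, RsmFit) else surrogate
        if factors is None:
            raise ValueError("polynomial surrogates need factors for coding")

        def f_poly(x: np.ndarray) -> float:
            coded = np.array([fac.code(v) for fac, v in zip(factors, x)])
            return float(model.predict(coded))

        return f_poly

    net, (x_norm, y_norm) = surrogate

    def f_net(x: np.ndarray) -> float:
        zn = forward(net, x_norm.transform(np.asarray(x, dtype=float)))
        return float(y_norm.inverse(np.array([[zn]]))[0, 0])

    return f_net


def optimize_surrogate(
    surrogate,
    bounds: Sequence[tuple[float, float]],
    config: GaConfig = GaConfig(),
    factors: Sequence[Factor] | None = None,
) -> tuple[np.ndarray, float, GaResult]:
    """Maximize a surrogate's predicted response over actual-unit bounds.

    The GA minimizes the negated prediction; the returned fitness is flipped
    back to the g/L scale.  Bounds extending beyond an ANN surrogate's
    normalizer range trigger an extrapolation warning, not an error.
    """
    f = surrogate_function(surrogate, factors)
    if not isinstance(surrogate, (RsmFit, PolynomialModel)):
        _, (x_norm, _) = surrogate
        lo = np.asarray(x_norm.lo)
        hi = np.asarray(x_norm.hi)
        b = np.asarray(bounds, dtype=float)
        if np.any(b[:, 0] < lo - 1e-9) or np.any(b[:, 1] > hi + 1e-9):
            warnings.warn(
                "GA bounds extend beyond the surrogate's training range; "
                "predictions there are extrapolations",
                stacklevel=2,
            )
    result = ga_minimize(lambda x: -f(x), bounds, config)
    best = result.best_point.copy()
    return best, -result.best_fitness, result
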