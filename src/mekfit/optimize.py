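"""Differential evolution under box constraints.

Maximum-likelihood fitting minimizes the hybrid objective with the classic
rand/1/bin scheme: mutant = x_r1 + F (x_r2 - x_r3) over three distinct
random members, binomial crossover with one guaranteed mutant coordinate,
reflection of out-of-bounds coordinates back into the box, and greedy
selection (the best member never worsens).

Coordinates whose box spans at least one decade of a positive range are
searched in log10 space (rate constants and scaling factors span one to two
decades); anything else, including ranges touching zero, stays linear.
Initial populations are therefore log-uniform per coordinate in the
transformed space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["FitConfig", "FitResult", "SearchSpace", "init_population",
           "de_generation", "fit", "fit_multistart"]

Objective = Callable[[np.ndarray], float]


@dataclass
class FitConfig:
    """Differential-evolution settings (robust defaults for ~30 dimensions)."""

    popsize: int = 50
    generations: int = 500
    mutation: float = 0.85
    crossover: float = 0.7
    seed: int = 0
    target_objective: Optional[float] = None  # stop early once reached
    n_runs: int = 1

    def __post_init__(self) -> None:
        if self.popsize < 4:
            raise ValueError("population size must be >= 4")
        if not 0 < self.mutation < 2:
            raise ValueError("mutation factor must be in (0, 2)")
        if not 0 < self.crossover <= 1:
            raise ValueError("crossover rate must be in (0, 1]")


@dataclass
class FitResult:
    """Outcome of one optimization run."""

    x: np.ndarray                 # best point, original scale
    fun: float                    # best objective
    history: List[float]          # per-generation best (non-increasing)
    n_evaluations: int
    seed: int
    label: str = ""
    names: List[str] = field(default_factory=list)

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.names, map(float, self.x)))


class SearchSpace:
    """Box bounds with per-coordinate linear/log10 search-space choice."""

    def __init__(self, bounds: Dict[str, Tuple[float, float]]):
        if not bounds:
            raise ValueError("empty bounds")
        self.names = list(bounds)
        lo = np.array([bounds[n][0] for n in self.names], dtype=float)
        hi = np.array([bounds[n][1] for n in self.names], dtype=float)
        if np.any(lo >= hi):
            bad = self.names[int(np.argmax(lo >= hi))]
            raise ValueError(f"lower bound >= upper bound for {bad!r}")
        self.lo, self.hi = lo, hi
        self.log = (lo > 0) & (hi / np.maximum(lo, 1e-300) >= 10.0)
        self.ilo = np.where(self.log, np.log10(np.where(self.log, lo, 1.0)), lo)
        self.ihi = np.where(self.log, np.log10(np.where(self.log, hi, 1.0)), hi)

    @property
    def dim(self) -> int:
        return len(self.names)

    def to_external(self, u: np.ndarray) -> np.ndarray:
        return np.where(self.log, 10.0 ** u, u)

    def to_internal(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.where(self.log, np.log10(np.maximum(x, 1e-300)), x)

    def reflect(self, u: np.ndarray) -> np.ndarray:
        """Fold out-of-bounds coordinates back into the box (triangle wave)."""
        lo, hi = self.ilo, self.ihi
        width = hi - lo
        y = np.mod(u - lo, 2.0 * width)
        y = np.where(y > width, 2.0 * width - y, y)
        return lo + y

    def contains(self, u: np.ndarray) -> bool:
        return bool(np.all(u >= self.ilo - 1e-12) and np.all(u <= self.ihi + 1e-12))


def init_population(
    space: SearchSpace, config: FitConfig, rng: np.random.Generator
) -> np.ndarray:
    """Independent uniform draws in the (log-transformed) box.

    Log-scaled coordinates are thereby log-uniform on the original scale;
    coordinates spanning less than a decade are uniform.
    """
    u = rng.uniform(size=(config.popsize, space.dim))
    return space.ilo + u * (space.ihi - space.ilo)


def de_generation(
    population: np.ndarray,
    fitness: np.ndarray,
    objective: Objective,
    space: SearchSpace,
    config: FitConfig,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray, int]:
    """One rand/1/bin generation with greedy selection.

    Returns the new population, its fitness, and the number of objective
    evaluations performed.  ``population`` lives in internal (search) space.
    """
    npop, dim = population.shape
    if npop < 4:
        raise ValueError("differential evolution needs a population of >= 4")
    n_eval = 0
    new_pop = population.copy()
    new_fit = fitness.copy()
    for i in range(npop):
        candidates = [j for j in range(npop) if j != i]
        r1, r2, r3 = rng.choice(candidates, size=3, replace=False)
        mutant = population[r1] + config.mutation * (
            population[r2] - population[r3]
        )
        cross = rng.uniform(size=dim) < config.crossover
        cross[rng.integers(dim)] = True  # at least one mutant coordinate
        trial = np.where(cross, mutant, population[i])
        trial = space.reflect(trial)
        f_trial = objective(space.to_external(trial))
        n_eval += 1
        if f_trial <= fitness[i]:
            new_pop[i] = trial
            new_fit[i] = f_trial
    return new_pop, new_fit, n_eval


def fit(
    objective: Objective,
    bounds: Dict[str, Tuple[float, float]],
    config: Optional[FitConfig] = None,
    x0: Optional[Sequence[float]] = None,
    label: str = "",
) -> FitResult:
    """Minimize ``objective`` over the box by differential evolution.

    ``objective`` receives points on the original scale.  ``x0`` (original
    scale) optionally replaces the first population member, which warm-starts
    the search.  Runs are deterministic for a given seed.
    """
    config = config or FitConfig()
    space = SearchSpace(bounds)
    rng = np.random.default_rng(config.seed)
    pop = init_population(space, config, rng)
    if x0 is not None:
        pop[0] = space.reflect(space.to_internal(np.asarray(x0, dtype=float)))
    fitness = np.array([objective(space.to_external(u)) for u in pop])
    n_eval = len(pop)
    history = [float(np.min(fitness))]
    for _ in range(config.generations):
        pop, fitness, ne = de_generation(
            pop, fitness, objective, space, config, rng
        )
        n_eval += ne
        history.append(float(np.min(fitness)))
        if (
            config.target_objective is not None
            and history[-1] <= config.target_objective
        ):
            break
    best = int(np.argmin(fitness))
    return FitResult(
        x=space.to_external(pop[best]),
        fun=float(fitness[best]),
        history=history,
        n_evaluations=n_eval,
        seed=config.seed,
        label=label,
        names=list(space.names),
    )


def fit_multistart(
    objective: Objective,
    bounds: Dict[str, Tuple[float, float]],
    config: Optional[FitConfig] = None,
) -> Tuple[FitResult, List[FitResult]]:
    """Independent runs from random feasible starts; returns (best, all)."""
    config = config or FitConfig()
    results = []
    for k in range(config.n_runs):
        run_cfg = FitConfig(
            popsize=config.popsize,
            generations=config.generations,
            mutation=config.mutation,
            crossover=config.crossover,
            seed=config.seed + k,
            target_objective=config.target_objective,
        )
        results.append(fit(objective, bounds, run_cfg, label=f"run{k}"))
    best = min(results, key=lambda r: r.fun)
    return best, results
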