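"""Constrained real-coded genetic algorithm with stochastic ranking.

The optimizer follows the iterative-start / stochastic-ranking / ensemble
crossover / just-generation-gap recipe for constrained problems:

1. draw a random initial population inside the log10 search box;
2. sample a parent subset uniformly without replacement;
3. generate children by ensemble (REX-style) crossover around the parent
   centroid, optionally shifted toward the better parents ("star" bias);
4. rank the children by stochastic ranking, which trades off the objective
   ``f`` against the constraint violation ``γ`` probabilistically;
5. replace the sampled parents with the best children (JGG), keeping the
   population size constant;
6. when neither the best feasible ``f`` nor the best ``γ`` has improved
   for a stall window, restart from a fresh random population while
   retaining the best individual found so far (iterative start).

Every stochastic operation consumes one explicitly passed NumPy Generator,
so runs with equal seeds are bit-identical.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd

from .plausibility import ConfigurationError, EvaluationResult

__all__ = [
    "GAConfig",
    "Individual",
    "GARun",
    "Problem",
    "FunctionProblem",
    "initialize_population",
    "rex_crossover",
    "stochastic_rank",
    "jgg_step",
    "optimize",
]

logger = logging.getLogger(__name__)


class Problem(Protocol):
    """Anything the GA can optimize: a box and an evaluator."""

    lower: np.ndarray
    upper: np.ndarray

    def evaluate(self, genome: np.ndarray) -> EvaluationResult: ...


@dataclass
class FunctionProblem:
    """Adapter wrapping plain callables ``f(x)`` and ``g(x)`` as a Problem."""

    lower: np.ndarray
    upper: np.ndarray
    objective: Callable[[np.ndarray], float]
    constraints: Callable[[np.ndarray], Sequence[float]] = lambda x: ()

    def evaluate(self, genome: np.ndarray) -> EvaluationResult:
        g = {f"g{i}": float(v) for i, v in enumerate(self.constraints(genome))}
        return EvaluationResult.from_f_and_g(self.objective(genome), g)


@dataclass(frozen=True)
class GAConfig:
    """Run-control knobs of the genetic algorithm.

    Defaults scale with the search dimension d: population 10·d, d+1
    parents, 4·d children, pf = 0.45 and a stall window of 50·d
    generations — standard values for JGG/REX with stochastic ranking.
    """

    population_size: int
    n_parents: int
    n_children: int
    pf: float = 0.45
    expansion_rate: float = 1.0
    stall_generations: int = 200
    max_evaluations: int = 10_000
    wall_clock_budget: float | None = None  # seconds
    seed: int = 0
    star_bias: bool = True

    def __post_init__(self) -> None:
        if self.n_parents > self.population_size:
            raise ConfigurationError("n_parents must not exceed population_size")
        if self.n_children < self.n_parents:
            raise ConfigurationError("n_children must be at least n_parents")
        if not 0.0 <= self.pf <= 1.0:
            raise ConfigurationError("pf must lie in [0, 1]")
        for name in ("population_size", "n_parents", "n_children",
                     "stall_generations", "max_evaluations"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    @classmethod
    def for_dimension(cls, d: int, seed: int = 0, **overrides) -> "GAConfig":
        defaults = dict(
            population_size=10 * d,
            n_parents=d + 1,
            n_children=4 * d,
            stall_generations=50 * d,
            seed=seed,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class Individual:
    genome: np.ndarray
    evaluation: EvaluationResult | None = None

    @property
    def evaluated(self) -> bool:
        return self.evaluation is not None


@dataclass
class GARun:
    """Result of one optimization run."""

    best: Individual
    history: pd.DataFrame  # generation, best_f, best_gamma, feasible_fraction, evaluations
    restarts: int
    seed: int
    n_evaluations: int

    @property
    def feasible(self) -> bool:
        return self.best.evaluation is not None and self.best.evaluation.feasible


def initialize_population(
    config: GAConfig,
    bounds: tuple[np.ndarray, np.ndarray],
    rng: np.random.Generator,
) -> list[Individual]:
    """Uniform random population inside the (log-space) box."""
    lower, upper = (np.asarray(b, dtype=float) for b in bounds)
    if np.all(upper <= lower):
        raise ConfigurationError("degenerate bounds: no axis has positive width")
    genomes = rng.uniform(lower, upper, size=(config.population_size, lower.size))
    return [Individual(g) for g in genomes]


def _reflect(x: np.ndarray, lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """Fold out-of-box coordinates back by reflection at the boundary."""
    width = upper - lower
    out = x.copy()
    free = width > 0
    y = np.mod(out[..., free] - lower[free], 2 * width[free])
    out[..., free] = lower[free] + np.minimum(y, 2 * width[free] - y)
    out[..., ~free] = lower[~free]
    return out


def rex_crossover(
    parents: Sequence[np.ndarray],
    n_children: int,
    expansion_rate: float,
    rng: np.random.Generator,
    weights: Sequence[float] | None = None,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[np.ndarray]:
    """Ensemble crossover: children around the parent centroid.

    Each child is ``c + Σ_i ξ_i (x_i − c̄)`` with ``ξ_i`` i.i.d. normal with
    mean 0 and standard deviation ``expansion_rate / sqrt(n_parents)``;
    ``c̄`` is the plain centroid and ``c`` is either the plain centroid
    (unbiased mode) or a ``weights``-weighted one (star bias toward better
    parents).  Children are repaired into the box by reflection.
    """
    if len(parents) < 2:
        raise ConfigurationError("ensemble crossover needs at least 2 parents")
    xs = np.asarray(parents, dtype=float)
    centroid = xs.mean(axis=0)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        base = (w[:, None] * xs).sum(axis=0) / w.sum()
    else:
        base = centroid
    xi = rng.normal(
        0.0, expansion_rate / math.sqrt(len(parents)), size=(n_children, len(parents))
    )
    children = base + xi @ (xs - centroid)
    if bounds is not None:
        children = _reflect(children, *bounds)
    return list(children)


def stochastic_rank(
    individuals: Sequence[Individual],
    pf: float,
    rng: np.random.Generator,
) -> list[int]:
    """Stochastic-ranking order (indices, best first).

    Repeated bubble sweeps over adjacent pairs: a pair is compared by the
    objective ``f`` when both members are feasible or, with probability
    ``pf``, regardless of feasibility; otherwise it is compared by the
    violation ``γ``.  Sweeps stop when a sweep performs no swap, or after
    N sweeps.
    """
    for ind in individuals:
        if not ind.evaluated:
            raise ConfigurationError("stochastic_rank requires evaluated individuals")
    order = list(range(len(individuals)))
    n = len(order)
    for _ in range(n):
        swapped = False
        for j in range(n - 1):
            a = individuals[order[j]].evaluation
            b = individuals[order[j + 1]].evaluation
            assert a is not None and b is not None
            by_f = (a.gamma == 0.0 and b.gamma == 0.0) or rng.random() < pf
            if (a.f_value > b.f_value) if by_f else (a.gamma > b.gamma):
                order[j], order[j + 1] = order[j + 1], order[j]
                swapped = True
        if not swapped:
            break
    return order


def _evaluate(problem: Problem, genome: np.ndarray) -> EvaluationResult:
    try:
        result = problem.evaluate(genome)
    except Exception as exc:  # simulation failure -> worst-possible rank
        logger.debug("evaluation failed, assigning infinite violation: %s", exc)
        return EvaluationResult.failed()
    return result


def _lexi_key(ev: EvaluationResult) -> tuple[float, float]:
    return (ev.gamma, ev.f_value)


def jgg_step(
    population: list[Individual],
    config: GAConfig,
    problem: Problem,
    rng: np.random.Generator,
) -> int:
    """One JGG generation, in place; returns the number of evaluations.

    Parents are sampled uniformly without replacement, children generated
    by REX crossover and ranked by stochastic ranking; the best
    ``n_parents`` children replace the sampled parents.
    """
    idx = rng.choice(len(population), size=config.n_parents, replace=False)
    parents = [population[i] for i in idx]
    weights = None
    if config.star_bias:
        # rank-weighted centroid shift toward the better parents
        order = sorted(
            range(len(parents)), key=lambda i: _lexi_key(parents[i].evaluation)  # type: ignore[arg-type]
        )
        weights = np.empty(len(parents))
        for rank, i in enumerate(order):
            weights[i] = len(parents) - rank
    genomes = rex_crossover(
        [p.genome for p in parents],
        config.n_children,
        config.expansion_rate,
        rng,
        weights=weights,
        bounds=(problem.lower, problem.upper),
    )
    children = [Individual(g, _evaluate(problem, g)) for g in genomes]
    order = stochastic_rank(children, config.pf, rng)
    for slot, child_idx in zip(idx, order[: config.n_parents]):
        population[slot] = children[child_idx]
    return len(children)


def optimize(problem: Problem, config: GAConfig) -> GARun:
    """Run the full iterative-start GA on a constrained problem.

    Stops at ``max_evaluations`` or the wall-clock budget.  The best
    individual is archived across restarts by the lexicographic (γ, f)
    order, so the archive never worsens.  If no feasible individual is
    ever found, the best-γ individual is returned (``GARun.feasible`` is
    then False).
    """
    rng = np.random.default_rng(config.seed)
    bounds = (np.asarray(problem.lower, float), np.asarray(problem.upper, float))
    t0 = time.monotonic()
    evaluations = 0
    restarts = 0
    best: Individual | None = None
    stall = 0
    history: list[dict] = []
    generation = 0

    def out_of_budget() -> bool:
        if evaluations >= config.max_evaluations:
            return True
        return (
            config.wall_clock_budget is not None
            and time.monotonic() - t0 > config.wall_clock_budget
        )

    def fresh_population() -> list[Individual]:
        nonlocal evaluations
        pop = initialize_population(config, bounds, rng)
        for ind in pop:
            ind.evaluation = _evaluate(problem, ind.genome)
        evaluations += len(pop)
        return pop

    population = fresh_population()
    while True:
        # archive update and stall accounting
        gen_best = min(population, key=lambda i: _lexi_key(i.evaluation))  # type: ignore[arg-type]
        if best is None or _lexi_key(gen_best.evaluation) < _lexi_key(best.evaluation):  # type: ignore[arg-type]
            best = Individual(gen_best.genome.copy(), gen_best.evaluation)
            stall = 0
        else:
            stall += 1
        feasible = [i for i in population if i.evaluation.feasible]  # type: ignore[union-attr]
        history.append(
            {
                "generation": generation,
                "best_f": min((i.evaluation.f_value for i in feasible), default=math.nan),
                "best_gamma": min(i.evaluation.gamma for i in population),
                "feasible_fraction": len(feasible) / len(population),
                "evaluations": evaluations,
            }
        )
        if out_of_budget():
            break
        if stall >= config.stall_generations:
            logger.info(
                "restart %d at generation %d (no improvement for %d generations)",
                restarts + 1, generation, stall,
            )
            restarts += 1
            stall = 0
            population = fresh_population()
            generation += 1
            continue
        evaluations += jgg_step(population, config, problem, rng)
        generation += 1

    assert best is not None
    return GARun(
        best=best,
        history=pd.DataFrame.from_records(history),
        restarts=restarts,
        seed=config.seed,
        n_evaluations=evaluations,
    )
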