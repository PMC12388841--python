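"""Genetic-algorithm maximization of a fitted surrogate over the design box.

Chromosomes are real-coded triples in natural units (temperature, time,
ethanol fraction).  Parents are drawn by fitness-proportionate roulette-wheel
selection on shifted fitnesses

    P(i) = (f_i - f_min + eps) / sum_j (f_j - f_min + eps),   eps = 1e-12,

recombined by single-point crossover at gene boundaries, and perturbed by
per-gene Gaussian mutation clipped to the bounds.  Elitism copies the best
individuals unchanged, which makes the best-so-far fitness monotone
non-decreasing.  Because a GA is stochastic, campaigns repeat the whole run
(default 30 times) and report the overall best plus between-run dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "GAConfig",
    "GARun",
    "GACampaign",
    "init_population",
    "roulette_select",
    "single_point_crossover",
    "mutate",
    "evolve",
    "run_repeated",
    "scenario_sweep",
]

_EPS = 1e-12


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings; bounds are per-gene (low, high) pairs."""

    bounds: tuple[tuple[float, float], ...]
    pop_size: int = 20
    max_generations: int = 100
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    mutation_sd: float = 0.1  # as a fraction of each gene's range
    elitism: int = 1
    stall_window: int = 25
    n_runs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 1 or self.max_generations < 1 or self.n_runs < 1:
            raise ValueError("pop_size, max_generations, n_runs must be positive")
        if not 0 <= self.elitism < self.pop_size:
            raise ValueError("need 0 <= elitism < pop_size")
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ValueError("rates must be in [0, 1]")
        if self.mutation_sd <= 0:
            raise ValueError("mutation_sd must be positive")
        for lo, hi in self.bounds:
            if lo > hi:
                raise ValueError(f"bounds must be ordered, got ({lo}, {hi})")


def _bounds_arrays(config: GAConfig) -> tuple[np.ndarray, np.ndarray]:
    b = np.asarray(config.bounds, dtype=float)
    return b[:, 0], b[:, 1]


def init_population(config: GAConfig, rng: np.random.Generator | int) -> np.ndarray:
    """Uniform random individuals inside the bounds, shape (pop_size, n_genes)."""
    rng = np.random.default_rng(rng)
    lo, hi = _bounds_arrays(config)
    return rng.uniform(lo, hi, size=(config.pop_size, len(config.bounds)))


def roulette_select(
    population: np.ndarray,
    fitnesses: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample k parents with replacement, probability proportional to
    shifted fitness (all-equal fitnesses degrade to uniform selection)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    f = np.asarray(fitnesses, dtype=float)
    finite = np.isfinite(f)
    if not finite.any():
        raise ValueError("no finite fitness in population")
    fmin = f[finite].min()
    w = np.where(finite, f - fmin + _EPS, 0.0)
    prob = w / w.sum()
    idx = rng.choice(len(f), size=k, replace=True, p=prob)
    return population[idx].copy()


def single_point_crossover(
    parent_a: np.ndarray, parent_b: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Swap suffixes at a uniform interior cut; genes are never modified."""
    a = np.asarray(parent_a, dtype=float).copy()
    b = np.asarray(parent_b, dtype=float).copy()
    if a.shape != b.shape:
        raise ValueError("parents must have equal length")
    L = len(a)
    if L < 2:
        return a, b
    cut = int(rng.integers(1, L))
    child_a = np.concatenate([a[:cut], b[cut:]])
    child_b = np.concatenate([b[:cut], a[cut:]])
    return child_a, child_b


def mutate(individual: np.ndarray, config: GAConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-gene Gaussian perturbation (sd = mutation_sd x gene range) applied
    with probability mutation_rate, then clipped to bounds."""
    lo, hi = _bounds_arrays(config)
    x = np.asarray(individual, dtype=float).copy()
    hit = rng.random(len(x)) < config.mutation_rate
    noise = rng.normal(0.0, config.mutation_sd * (hi - lo))
    x[hit] += noise[hit] if np.ndim(noise) else noise
    return np.clip(x, lo, hi)


@dataclass
class GARun:
    """One GA run: per-generation best fitness and the best individual."""

    best_per_generation: list[tuple[int, float]]
    best_individual: np.ndarray
    best_fitness: float
    converged_at: int
    n_nonfinite: int = 0


def evolve(
    surrogate: Callable[[np.ndarray], float],
    config: GAConfig,
    rng: np.random.Generator | int | None = None,
) -> GARun:
    """Run one generational GA maximizing ``surrogate`` over the box.

    The surrogate maps a natural-unit gene vector to a scalar fitness;
    non-finite outputs are treated as -inf (the individual is never
    selected as elite).  Stops at ``max_generations`` or when the best-so-far
    has not improved for ``stall_window`` generations.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    lo, hi = _bounds_arrays(config)
    n_nonfinite = 0

    def evaluate(pop: np.ndarray) -> np.ndarray:
        nonlocal n_nonfinite
        f = np.array([float(surrogate(ind)) for ind in pop])
        bad = ~np.isfinite(f)
        n_nonfinite += int(bad.sum())
        f[bad] = -np.inf
        return f

    pop = init_population(config, rng)
    fit = evaluate(pop)
    best_i = int(np.argmax(fit))
    best_x, best_f = pop[best_i].copy(), float(fit[best_i])
    trace: list[tuple[int, float]] = [(0, best_f)]
    converged_at = 0
    stall = 0

    for gen in range(1, config.max_generations + 1):
        order = np.argsort(-fit, kind="stable")
        elite = pop[order[: config.elitism]].copy()
        n_child = config.pop_size - config.elitism
        children = []
        while len(children) < n_child:
            pa, pb = roulette_select(pop, fit, 2, rng)
            if rng.random() < config.crossover_rate:
                ca, cb = single_point_crossover(pa, pb, rng)
            else:
                ca, cb = pa.copy(), pb.copy()
            children.append(mutate(ca, config, rng))
            if len(children) < n_child:
                children.append(mutate(cb, config, rng))
        pop = np.vstack([elite, np.array(children)]) if len(elite) else np.array(children)
        fit = evaluate(pop)
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_f:
            best_f = float(fit[gen_best])
            best_x = pop[gen_best].copy()
            converged_at = gen
            stall = 0
        else:
            stall += 1
        trace.append((gen, best_f))
        if stall >= config.stall_window:
            break
    return GARun(
        best_per_generation=trace,
        best_individual=best_x,
        best_fitness=best_f,
        converged_at=converged_at,
        n_nonfinite=n_nonfinite,
    )


@dataclass
class GACampaign:
    """Summary over repeated independent GA runs."""

    runs: list[GARun]
    best_individual: np.ndarray
    best_fitness: float
    fitness_mean: float
    fitness_sd: float
    pop_size: int

    @property
    def per_run_best(self) -> np.ndarray:
        return np.array([r.best_fitness for r in self.runs])


def run_repeated(
    surrogate: Callable[[np.ndarray], float],
    config: GAConfig,
    n_runs: int | None = None,
) -> GACampaign:
    """Repeat ``evolve`` from independent seeds and summarize.

    Repetition raises the chance of hitting the global optimum of a
    multimodal surrogate; per-run seeds are spawned deterministically from
    ``config.seed``.
    """
    n_runs = config.n_runs if n_runs is None else n_runs
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    runs = []
    for i in range(n_runs):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(config.pop_size, i)))
        runs.append(evolve(surrogate, config, rng))
    bests = np.array([r.best_fitness for r in runs])
    top = int(np.argmax(bests))
    return GACampaign(
        runs=runs,
        best_individual=runs[top].best_individual.copy(),
        best_fitness=float(bests[top]),
        fitness_mean=float(bests.mean()),
        fitness_sd=float(bests.std(ddof=1)) if len(bests) > 1 else 0.0,
        pop_size=config.pop_size,
    )


def scenario_sweep(
    surrogate: Callable[[np.ndarray], float],
    config: GAConfig,
    pop_sizes: Sequence[int] = (5, 10, 20, 50),
) -> dict[int, GACampaign]:
    """Run one repeated campaign per population size (elitism capped below
    each size); returns {pop_size: campaign}."""
    out: dict[int, GACampaign] = {}
    for ps in pop_sizes:
        cfg = replace(config, pop_size=ps, elitism=min(config.elitism, ps - 1))
        out[ps] = run_repeated(surrogate, cfg)
    return out
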