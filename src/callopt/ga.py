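"""Genetic algorithm over the 4-D hormone-dose box.

Real-valued encoding: an individual is a vector of (BAP, KIN, NAA, IBA)
concentrations in mg/L.  Generations follow the classic loop —
evaluate, roulette-wheel select, blend crossover, Gaussian mutation, with
elitism carrying the best individuals through unchanged, which makes the
best-so-far fitness monotonically non-decreasing.  Termination is a fixed
generation budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# roulette floor: fraction of the fitness range granted to the worst
# individual so it keeps a nonzero selection probability
_FLOOR = 1e-9


@dataclass
class GAConfig:
    """Settings for one GA run (defaults sized for a 4-D dose box)."""

    population_size: int = 60
    max_generations: int = 200
    crossover_rate: float = 0.9
    mutation_rate: float = 0.15
    mutation_sd: float = 0.1  # mg/L
    elitism_count: int = 2
    bounds: tuple = ((0.0, 2.0),) * 4
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.crossover_rate <= 1 or not 0 <= self.mutation_rate <= 1:
            raise ValueError("crossover and mutation rates must lie in [0, 1]")
        if not 0 <= self.elitism_count < self.population_size:
            raise ValueError("elitism_count must be < population_size")
        for lo, hi in self.bounds:
            if lo >= hi:
                raise ValueError(f"invalid bound ({lo}, {hi})")


@dataclass
class GAResult:
    """Best dose vector ever evaluated and the per-generation trace."""

    best_doses: np.ndarray
    best_fitness: float
    history: list = field(default_factory=list)  # (generation, best, mean)
    generations_run: int = 0

    def as_dict(self) -> dict:
        return {
            "best_doses": [float(v) for v in self.best_doses],
            "best_fitness": float(self.best_fitness),
            "generations_run": self.generations_run,
            "history": [
                {"generation": g, "best": b, "mean": m} for g, b, m in self.history
            ],
        }


def roulette_select(fitnesses, n_parents, rng) -> np.ndarray:
    """Sample parent indices with probability proportional to fitness.

    Fitnesses are shifted so the minimum maps to a small positive floor,
    which handles negative values and ties; an all-equal population is
    sampled uniformly.
    """
    f = np.asarray(fitnesses, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("fitnesses must be finite for roulette selection")
    span = f.max() - f.min()
    if span == 0:
        p = np.full(len(f), 1.0 / len(f))
    else:
        mass = f - f.min() + _FLOOR * span
        p = mass / mass.sum()
    return rng.choice(len(f), size=n_parents, p=p)


def crossover_blend(parent_a, parent_b, rate, rng):
    """Per-gene arithmetic blend with probability ``rate``.

    Children are convex combinations of the parents (alpha drawn per gene),
    so they always stay inside any box containing both parents.
    """
    a = np.asarray(parent_a, dtype=float)
    b = np.asarray(parent_b, dtype=float)
    if rng.random() >= rate:
        return a.copy(), b.copy()
    alpha = rng.random(a.shape)
    return alpha * a + (1 - alpha) * b, alpha * b + (1 - alpha) * a


def mutate_gaussian(individual, rate, sd, bounds, rng):
    """Perturb each gene with probability ``rate`` by N(0, sd), clipped to bounds."""
    x = np.asarray(individual, dtype=float).copy()
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    hit = rng.random(x.shape) < rate
    x = np.where(hit, x + rng.normal(0.0, sd, x.shape) if sd > 0 else x, x)
    return np.clip(x, lo, hi)


def ga_optimize(fitness, config: GAConfig | None = None,
                initial_points=None) -> GAResult:
    """Maximise ``fitness`` over the bounds box.

    ``fitness`` maps an (n x d) array of dose vectors to an (n,) array of
    finite scores.  ``initial_points`` optionally seeds part of the first
    generation with known dose combinations (e.g. the screened treatments),
    so the search starts no worse than the best design point; the rest of
    the population is drawn uniformly.  Returns the best individual ever
    evaluated.
    """
    cfg = config or GAConfig()
    rng = np.random.default_rng(cfg.seed)
    lo = np.array([b[0] for b in cfg.bounds])
    hi = np.array([b[1] for b in cfg.bounds])
    d = len(cfg.bounds)
    pop = rng.uniform(lo, hi, (cfg.population_size, d))
    if initial_points is not None:
        pts = np.clip(np.atleast_2d(np.asarray(initial_points, dtype=float)), lo, hi)
        pop[: min(len(pts), cfg.population_size)] = pts[: cfg.population_size]

    def evaluate(P):
        f = np.asarray(fitness(P), dtype=float).ravel()
        if not np.all(np.isfinite(f)):
            bad = P[~np.isfinite(f)][0]
            raise ValueError(f"non-finite fitness at doses {bad.tolist()}")
        return f

    fit = evaluate(pop)
    best_idx = int(np.argmax(fit))
    best_x, best_f = pop[best_idx].copy(), float(fit[best_idx])
    # history holds the per-generation population best (not best-so-far):
    # its monotonicity is a genuine consequence of elitism
    history = [(0, float(fit[best_idx]), float(fit.mean()))]

    for gen in range(1, cfg.max_generations + 1):
        elite_idx = np.argsort(-fit)[: cfg.elitism_count]
        elites = pop[elite_idx].copy()
        n_children = cfg.population_size - cfg.elitism_count
        parents = roulette_select(fit, 2 * ((n_children + 1) // 2), rng)
        children = []
        for i in range(0, len(parents), 2):
            ca, cb = crossover_blend(pop[parents[i]], pop[parents[i + 1]],
                                     cfg.crossover_rate, rng)
            children.extend([ca, cb])
        children = np.array(children[:n_children])
        children = np.array([
            mutate_gaussian(c, cfg.mutation_rate, cfg.mutation_sd, cfg.bounds, rng)
            for c in children
        ])
        pop = np.vstack([elites, children])
        fit = evaluate(pop)
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_f:
            best_x, best_f = pop[gen_best].copy(), float(fit[gen_best])
        history.append((gen, float(fit[gen_best]), float(fit.mean())))

    return GAResult(
        best_doses=best_x,
        best_fitness=best_f,
        history=history,
        generations_run=cfg.max_generations,
    )
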