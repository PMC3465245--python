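"""A small real-valued genetic algorithm.

Used to train the 24 tier weights of the coverage predictor (and the 26-gene
variant that adds two channel-mixing weights). Genomes are float vectors
bounded to a box; selection is tournament, crossover uniform, mutation
per-gene Gaussian, and the single best individual is carried over unchanged
(elitism), which makes the best-fitness trace non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["GAConfig", "run_ga"]


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 80
    generations: int = 100
    crossover_prob: float = 0.9
    mutation_prob: float = 0.02  # per gene
    mutation_sigma: float = 0.1
    elitism: int = 1
    tournament_size: int = 3
    bounds: tuple[float, float] = (0.0, 1.0)


def run_ga(
    fitness: Callable[[np.ndarray], float],
    n_genes: int,
    cfg: GAConfig | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Maximize ``fitness`` over [lo, hi]^n_genes.

    Returns ``(best_genome, history)`` where history[g] is the best fitness
    seen up to generation g (non-decreasing by elitism). Deterministic for
    a given seed and config.
    """
    cfg = cfg or GAConfig()
    rng = np.random.default_rng(seed)
    lo, hi = cfg.bounds
    pop = rng.uniform(lo, hi, size=(cfg.population_size, n_genes))
    fit = np.array([fitness(ind) for ind in pop])
    history = np.empty(cfg.generations + 1)
    history[0] = fit.max()

    for gen in range(1, cfg.generations + 1):
        order = np.argsort(fit)[::-1]
        elite = pop[order[: cfg.elitism]].copy()
        n_children = cfg.population_size - cfg.elitism

        # tournament selection of parents
        idx = rng.integers(0, cfg.population_size, size=(2 * n_children, cfg.tournament_size))
        winners = idx[np.arange(2 * n_children), np.argmax(fit[idx], axis=1)]
        parents = pop[winners].reshape(2, n_children, n_genes)

        # uniform crossover
        take_b = rng.random((n_children, n_genes)) < 0.5
        cross = rng.random(n_children) < cfg.crossover_prob
        children = parents[0].copy()
        swap = take_b & cross[:, None]
        children[swap] = parents[1][swap]

        # per-gene Gaussian mutation, clipped to bounds
        mutate = rng.random((n_children, n_genes)) < cfg.mutation_prob
        noise = rng.normal(0.0, cfg.mutation_sigma, size=(n_children, n_genes))
        children = np.clip(children + mutate * noise, lo, hi)

        pop = np.vstack([elite, children])
        child_fit = np.array([fitness(ind) for ind in children])
        fit = np.concatenate([fit[order[: cfg.elitism]], child_fit])
        history[gen] = max(history[gen - 1], fit.max())

    return pop[np.argmax(fit)].copy(), history
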