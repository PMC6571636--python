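"""Genetic-algorithm descriptor selection with a CP-ANN wrapper fitness.

Chromosomes are binary inclusion vectors over the candidate descriptors. The
fitness of a chromosome is the product MCC_TR x MCC_TE, where each factor is
the arithmetic mean of the per-class one-vs-rest Matthews correlation
coefficients of a CP-ANN trained on the training set restricted to the
selected descriptors and evaluated on the respective set. Using the product
rewards models that are simultaneously well-fitted and well-generalising.

The search is steady-state: each generation two parents are drawn by
rank-weighted roulette, recombined by uniform crossover, mutated by
independent bit flips, and the offspring replaces the weakest member of the
population outside the elite (the ``survivors`` best are never replaced).
Fitness evaluations are memoised by bit pattern and every CP-ANN is trained
with the same seed, so the fitness landscape is deterministic within a run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cpannet.data import CLASS_NAMES
from cpannet.metrics import mean_mcc
from cpannet.model import predict_batch, train_cpann
from cpannet.som import SOMConfig

__all__ = ["Chromosome", "GAConfig", "evaluate_fitness", "crossover", "mutate", "run_ga"]


@dataclass
class Chromosome:
    """Binary descriptor-inclusion vector with its (evaluated) fitness."""

    bits: np.ndarray
    fitness: float = math.nan

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())

    def selected_names(self, names) -> list[str]:
        return [str(n) for n, b in zip(names, self.bits) if b]


@dataclass(frozen=True)
class GAConfig:
    """GA and fitness-network parameters.

    Defaults follow the reference search: 95 chromosomes, 150 generations,
    20 survivors, 2% mutation, learning rates 0.6 -> 0.001. The fitness
    CP-ANN uses a reduced grid (20x20, 150 epochs by default) — the full
    43x43/600 network is reserved for the final refit. ``initial_genes``
    is the number of bits set at initialisation; ``None`` means half of the
    candidate descriptors.
    """

    population_size: int = 95
    generations: int = 150
    survivors: int = 20
    mutation_rate: float = 0.02
    initial_genes: int | None = None
    a_max: float = 0.6
    a_min: float = 0.001
    grid_rows: int = 20
    grid_cols: int = 20
    epochs: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.survivors >= self.population_size:
            raise ValueError("survivors must be smaller than population_size")
        if self.survivors < 1:
            raise ValueError("survivors must be >= 1")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")

    def som_config(self) -> SOMConfig:
        return SOMConfig(rows=self.grid_rows, cols=self.grid_cols, t_max=self.epochs,
                         a_max=self.a_max, a_min=self.a_min, seed=self.seed)


def evaluate_fitness(chromosome: Chromosome | np.ndarray, x_tr: pd.DataFrame,
                     labels_tr: pd.Series, x_te: pd.DataFrame, labels_te: pd.Series,
                     ga_config: GAConfig,
                     classes: tuple[str, ...] = CLASS_NAMES) -> float:
    """MCC_TR x MCC_TE of a CP-ANN on the chromosome's descriptor subset.

    Each MCC is the mean of the per-class one-vs-rest MCCs. An all-zero
    chromosome is unevaluable and gets the -inf sentinel rather than an
    exception.
    """
    bits = chromosome.bits if isinstance(chromosome, Chromosome) else \
        np.asarray(chromosome, dtype=bool)
    if bits.shape[0] != x_tr.shape[1]:
        raise ValueError("chromosome length does not match the descriptor count")
    if not bits.any():
        return -math.inf
    cols = list(x_tr.columns[bits])
    model = train_cpann(x_tr[cols], labels_tr, config=ga_config.som_config(),
                        classes=classes)
    _, frame_tr = predict_batch(model, x_tr[cols], labels_tr)
    _, frame_te = predict_batch(model, x_te[cols], labels_te)
    mcc_tr = mean_mcc(list(frame_tr["true"]), list(frame_tr["predicted"]), classes)
    mcc_te = mean_mcc(list(frame_te["true"]), list(frame_te["predicted"]), classes)
    return mcc_tr * mcc_te


def crossover(parent_a: np.ndarray, parent_b: np.ndarray,
              rng: np.random.Generator) -> np.ndarray:
    """Uniform crossover: each bit copied from a uniformly chosen parent."""
    a = np.asarray(parent_a, dtype=bool)
    b = np.asarray(parent_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("parents must have equal length")
    take_a = rng.random(a.shape[0]) < 0.5
    return np.where(take_a, a, b)


def mutate(bits: np.ndarray, mutation_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each bit independently with probability ``mutation_rate``."""
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must be in [0, 1]")
    bits = np.asarray(bits, dtype=bool)
    flips = rng.random(bits.shape[0]) < mutation_rate
    return bits ^ flips


def _rank_roulette(fitnesses: list[float], rng: np.random.Generator) -> tuple[int, int]:
    """Two distinct parent indices, probability proportional to fitness rank.

    Rank weighting (worst rank weight 1, best weight P) is robust to
    negative MCC products, which plain fitness-proportional selection is not.
    """
    order = np.argsort(np.asarray(fitnesses), kind="stable")
    weights = np.empty(len(fitnesses))
    weights[order] = np.arange(1, len(fitnesses) + 1)
    p = weights / weights.sum()
    return tuple(rng.choice(len(fitnesses), size=2, replace=False, p=p))


def run_ga(x_tr: pd.DataFrame, labels_tr: pd.Series, x_te: pd.DataFrame,
           labels_te: pd.Series, config: GAConfig,
           classes: tuple[str, ...] = CLASS_NAMES,
           ) -> tuple[Chromosome, pd.DataFrame]:
    """Steady-state GA over descriptor subsets; returns best-ever + history.

    The population starts with ``population_size`` chromosomes of
    ``initial_genes`` random bits each. Each generation produces one
    offspring (parent selection -> uniform crossover -> bit-flip mutation ->
    fitness evaluation) which replaces the weakest non-elite member. History
    rows: (generation, best_fitness, mean_fitness); generation 0 is the
    initial population. Deterministic for a fixed ``config.seed``.
    """
    n_desc = x_tr.shape[1]
    if n_desc < 1:
        raise ValueError("need at least one candidate descriptor")
    k0 = config.initial_genes if config.initial_genes is not None else max(1, n_desc // 2)
    if not 1 <= k0 <= n_desc:
        raise ValueError("initial_genes must be in [1, n_descriptors]")
    rng = np.random.default_rng(config.seed)

    cache: dict[bytes, float] = {}

    def fitness(bits: np.ndarray) -> float:
        key = np.packbits(bits).tobytes()
        if key not in cache:
            cache[key] = evaluate_fitness(bits, x_tr, labels_tr, x_te, labels_te,
                                          config, classes)
        return cache[key]

    population: list[np.ndarray] = []
    for _ in range(config.population_size):
        bits = np.zeros(n_desc, dtype=bool)
        bits[rng.choice(n_desc, size=k0, replace=False)] = True
        population.append(bits)
    fitnesses = [fitness(b) for b in population]

    def snapshot(gen: int) -> dict:
        finite = [f for f in fitnesses if math.isfinite(f)]
        return {"generation": gen, "best_fitness": max(fitnesses),
                "mean_fitness": float(np.mean(finite)) if finite else math.nan}

    history = [snapshot(0)]
    best_bits = population[int(np.argmax(fitnesses))].copy()
    best_fit = max(fitnesses)

    for gen in range(1, config.generations + 1):
        ia, ib = _rank_roulette(fitnesses, rng)
        child = mutate(crossover(population[ia], population[ib], rng),
                       config.mutation_rate, rng)
        child_fit = fitness(child)
        order = np.argsort(np.asarray(fitnesses), kind="stable")
        weakest = int(order[0])  # never in the elite since survivors < population
        population[weakest] = child
        fitnesses[weakest] = child_fit
        if child_fit > best_fit:
            best_fit, best_bits = child_fit, child.copy()
        history.append(snapshot(gen))

    return Chromosome(bits=best_bits, fitness=best_fit), pd.DataFrame(history)
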