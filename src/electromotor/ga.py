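"""Steady-state genetic algorithm over the 20 synaptic parameters.

The genome is the concatenation of (alpha, beta, g_syn, t_max) for the
five projections in the fixed order IS_DP, IS_PCN, ES_DP, ES_PCN, ES_CDP.
Each generation an offspring pool the size of the population is created by
uniform crossover and per-gene Gaussian mutation, merged with the parents,
evaluated in full, ranked, and truncated back to the population size; the
elite fraction is retained unconditionally, so the best fitness never
decreases.  Bounds keep excitatory conductances non-negative and
inhibitory ones non-positive; every operator clips to the bounds.

Evaluation is a pure function of (genome, evaluation seed), so runs are
reproducible and could be parallelised without changing results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import network as net
from . import patterns as pat
from .errors import ElectromotorError
from .synapse import SynapseParams

logger = logging.getLogger(__name__)

#: Genome layout: synapse order and per-synapse parameter order.
GENOME_SYNAPSES = ("IS_DP", "IS_PCN", "ES_DP", "ES_PCN", "ES_CDP")
GENOME_FIELDS = ("alpha", "beta", "g_syn", "t_max")
GENOME_LENGTH = len(GENOME_SYNAPSES) * len(GENOME_FIELDS)


def genome_from_synapses(synapses: dict[str, SynapseParams]) -> np.ndarray:
    """Flatten a synapse table into the 20-value genome."""
    return np.array(
        [
            getattr(synapses[name], f)
            for name in GENOME_SYNAPSES
            for f in GENOME_FIELDS
        ],
        dtype=float,
    )


def synapses_from_genome(
    genome: np.ndarray, template: dict[str, SynapseParams]
) -> dict[str, SynapseParams]:
    """Rebuild a synapse table from a genome, keeping non-evolved fields
    (threshold, reversal potential, transmitter concentration, wiring)
    from the template."""
    genome = np.asarray(genome, dtype=float)
    if genome.shape != (GENOME_LENGTH,):
        raise ValueError(f"genome must have shape ({GENOME_LENGTH},), got {genome.shape}")
    out: dict[str, SynapseParams] = {}
    for i, name in enumerate(GENOME_SYNAPSES):
        vals = dict(zip(GENOME_FIELDS, genome[4 * i: 4 * i + 4]))
        out[name] = replace(template[name], **vals)
    return out


def default_bounds(reference: np.ndarray | None = None) -> np.ndarray:
    """Wide per-parameter bound intervals, shape (20, 2).

    Rates and release times get broad positive ranges; conductances are
    sign-constrained by synapse role (IS_* <= 0 <= ES_*).  When a
    reference genome is given the intervals are additionally widened to
    contain it.
    """
    bounds = np.empty((GENOME_LENGTH, 2))
    for i, name in enumerate(GENOME_SYNAPSES):
        base = 4 * i
        bounds[base + 0] = (1e-3, 10.0)      # alpha
        bounds[base + 1] = (1e-4, 1.0)       # beta
        bounds[base + 2] = (-1.0, 0.0) if name.startswith("IS") else (0.0, 1.0)
        bounds[base + 3] = (1.0, 500.0)      # t_max
    if reference is not None:
        bounds[:, 0] = np.minimum(bounds[:, 0], reference)
        bounds[:, 1] = np.maximum(bounds[:, 1], reference)
    return bounds


def narrowed_bounds(
    center: np.ndarray, bounds: np.ndarray, fraction: float = 0.25
) -> np.ndarray:
    """Bounds shrunk around ``center`` to ``fraction`` of each interval,
    for a refinement stage seeded with a previous best."""
    width = (bounds[:, 1] - bounds[:, 0]) * fraction * 0.5
    lo = np.clip(center - width, bounds[:, 0], bounds[:, 1])
    hi = np.clip(center + width, bounds[:, 0], bounds[:, 1])
    return np.column_stack([lo, hi])


@dataclass
class Individual:
    """One candidate synaptic configuration and its (optional) fitness."""

    genome: np.ndarray
    fitness: pat.FitnessReport | None = None

    def __post_init__(self) -> None:
        self.genome = np.asarray(self.genome, dtype=float)
        if self.genome.shape != (GENOME_LENGTH,):
            raise ValueError(
                f"genome must have {GENOME_LENGTH} values, got {self.genome.shape}"
            )


@dataclass(frozen=True)
class GAConfig:
    """Settings of the steady-state GA."""

    bounds: np.ndarray
    population_size: int = 100
    elite_fraction: float = 0.10
    crossover_prob: float = 0.9
    mutation_prob: float = 0.1
    mutation_scale: float = 0.1
    max_generations: int = 200
    stop_fitness_ratio: float = 3.0
    perturb_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        b = np.asarray(self.bounds, dtype=float)
        if b.shape != (GENOME_LENGTH, 2):
            raise ValueError(f"bounds must have shape ({GENOME_LENGTH}, 2), got {b.shape}")
        if np.any(b[:, 0] > b[:, 1]):
            raise ValueError("bounds must satisfy lo <= hi")
        object.__setattr__(self, "bounds", b)
        if not 0 < self.elite_fraction < 1:
            raise ValueError(f"elite_fraction must be in (0, 1), got {self.elite_fraction}")
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")


def clip_to_bounds(genome: np.ndarray, config: GAConfig) -> np.ndarray:
    return np.clip(genome, config.bounds[:, 0], config.bounds[:, 1])


def initialize_population(
    config: GAConfig,
    seed_individual: Individual,
    rng: np.random.Generator,
) -> list[Individual]:
    """Seed individual plus seeded random perturbations of it.

    Each clone's genes are perturbed by Gaussian noise with standard
    deviation ``perturb_scale`` times the bound interval, then clipped.
    """
    g0 = seed_individual.genome
    if np.any(g0 < config.bounds[:, 0]) or np.any(g0 > config.bounds[:, 1]):
        raise ValueError("seed individual lies outside the configured bounds")
    width = config.bounds[:, 1] - config.bounds[:, 0]
    population = [Individual(genome=g0.copy())]
    for _ in range(config.population_size - 1):
        noise = rng.normal(0.0, config.perturb_scale * width)
        population.append(Individual(genome=clip_to_bounds(g0 + noise, config)))
    return population


def crossover(
    parent_a: Individual,
    parent_b: Individual,
    rng: np.random.Generator,
) -> Individual:
    """Uniform per-gene crossover: each gene taken from either parent."""
    mask = rng.random(GENOME_LENGTH) < 0.5
    return Individual(genome=np.where(mask, parent_a.genome, parent_b.genome))


def mutate(
    individual: Individual, rng: np.random.Generator, config: GAConfig
) -> Individual:
    """Per-gene Gaussian mutation with probability ``mutation_prob``,
    scale ``mutation_scale`` of the bound interval, clipped to bounds."""
    genome = individual.genome.copy()
    width = config.bounds[:, 1] - config.bounds[:, 0]
    mask = rng.random(GENOME_LENGTH) < config.mutation_prob
    if mask.any():
        genome[mask] += rng.normal(0.0, config.mutation_scale * width[mask])
        genome = clip_to_bounds(genome, config)
    return Individual(genome=genome)


def _tournament(
    population: list[Individual],
    scores: list[float],
    rng: np.random.Generator,
) -> Individual:
    i, j = rng.integers(0, len(population), size=2)
    return population[i] if scores[i] >= scores[j] else population[j]


def evolve(
    config: GAConfig,
    evaluate,
    seed_genome: np.ndarray,
) -> tuple[Individual, pd.DataFrame]:
    """Run the steady-state loop and return the best individual + history.

    ``evaluate(genome) -> float | FitnessReport`` must be deterministic.
    Each generation: an offspring pool of ``population_size`` individuals
    is bred by tournament selection, uniform crossover and Gaussian
    mutation, merged with the parents, everything is (re-)evaluated and
    ranked (ties broken by position, earlier first), and the population is
    truncated back to size with the elite always retained.  The loop stops
    at ``max_generations`` or once the best fitness reaches
    ``stop_fitness_ratio`` times the seed genome's fitness.

    An evaluation that raises is logged and scored as worst-case (0), so a
    pathological genome cannot abort a long run.
    """
    rng = np.random.default_rng(config.seed)
    population = initialize_population(config, Individual(genome=np.asarray(seed_genome, float)), rng)

    def score(ind: Individual) -> float:
        try:
            result = evaluate(ind.genome)
        except ElectromotorError as exc:
            logger.warning("evaluation failed, assigning worst-case fitness: %s", exc)
            ind.fitness = None
            return 0.0
        if isinstance(result, pat.FitnessReport):
            ind.fitness = result
            return result.total
        return float(result)

    initial_fitness = score(population[0])
    stop_at = config.stop_fitness_ratio * initial_fitness
    # scores of the current population, used for parent selection; the
    # initial population is evaluated once before the loop, afterwards the
    # merged pool (parents + offspring) is evaluated in full each
    # generation, as the steady-state scheme prescribes
    scores = [score(ind) for ind in population]

    history = []
    best = population[0]
    best_score = max(scores)
    for generation in range(config.max_generations):
        offspring = []
        for _ in range(config.population_size):
            pa = _tournament(population, scores, rng)
            if rng.random() < config.crossover_prob:
                pb = _tournament(population, scores, rng)
                child = crossover(pa, pb, rng)
            else:
                child = Individual(genome=pa.genome.copy())
            offspring.append(mutate(child, rng, config))
        merged = population + offspring
        merged_scores = [score(ind) for ind in merged]
        order = sorted(range(len(merged)), key=lambda i: (-merged_scores[i], i))
        population = [merged[i] for i in order[: config.population_size]]
        scores = [merged_scores[i] for i in order[: config.population_size]]
        # truncation keeps every top-ranked parent, so the elite fraction
        # survives unconditionally and the best fitness cannot decrease
        if scores[0] >= best_score:
            best = population[0]
            best_score = scores[0]
        history.append(
            {
                "generation": generation,
                "best": best_score,
                "mean": float(np.mean(scores)),
                "sd": float(np.std(scores)),
            }
        )
        if initial_fitness > 0 and best_score >= stop_at:
            break
    return best, pd.DataFrame(history)


def network_evaluator(
    network_config: net.NetworkConfig,
    protocols: dict[str, net.StimulationProtocol],
    targets: dict[str, pat.TargetSet],
    sim_seed: int = 0,
):
    """Build the real fitness function: simulate the four cases with the
    candidate synapses and score the four-pattern fitness.

    The returned callable maps a genome to a :class:`FitnessReport`; the
    simulation seed is fixed so evaluation is a pure function of the
    genome.
    """
    template = network_config.synapses

    def evaluate(genome: np.ndarray) -> pat.FitnessReport:
        synapses = synapses_from_genome(genome, template)
        cfg = replace(network_config, synapses=synapses)
        simulated: dict[str, net.SPISequence] = {}
        for label in pat.PATTERNS:
            result = net.simulate(cfg, protocols[label], seed=sim_seed)
            onset, end = net.protocol_display_window(protocols[label])
            simulated[label] = net.display_spi(result, onset, end)
        return pat.fitness_total(simulated, targets)

    return evaluate


def evolve_staged(
    stages: list[GAConfig],
    evaluate,
    seed_genome: np.ndarray,
) -> tuple[Individual, pd.DataFrame]:
    """Run several GA stages sequentially, each seeded with the previous
    best (e.g. one wide-bounds exploration stage then a narrowed
    refinement stage).  Returns the final best and concatenated history."""
    genome = np.asarray(seed_genome, dtype=float)
    histories = []
    best = Individual(genome=genome)
    for k, stage in enumerate(stages):
        best, hist = evolve(stage, evaluate, genome)
        hist = hist.assign(stage=k)
        histories.append(hist)
        genome = best.genome
    return best, pd.concat(histories, ignore_index=True)
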