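"""Evolutionary selection of merging groups.

A chromosome is an integer vector of length n (the number of sub-data sets);
gene i assigns sub-data set i to one of g merging groups, so a chromosome is
a partition of the pool into at most g disjoint groups.  The search follows
the classic generational loop (the EASimple scheme): tournament selection,
uniform crossover on consecutive pairs, uniform integer mutation, evaluation
of modified individuals, full replacement; a hall of fame of size one keeps
the best individual ever seen.

Group labels are interchangeable, so fitness is cached on a canonical
relabelling of the chromosome, and scored groups are additionally cached on
their membership set — the same subset combination is never scaled twice.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .datasets import SubDataset
from .fitness import MIN_FITNESS, FitnessReport, FitnessWeights, GroupScore, score_group, score_individual
from .merge import merge_group
from .scaling import scale_group
from .shells import ShellScheme
from .stats import compute_stats

logger = logging.getLogger(__name__)

__all__ = [
    "GAParams",
    "GARunRecord",
    "GroupEvaluator",
    "init_population",
    "uniform_crossover",
    "uniform_mutation",
    "tournament_select",
    "canonical_form",
    "evolve",
]


@dataclass(frozen=True)
class GAParams:
    population_size: int = 20
    generations: int = 300
    p_crossover: float = 0.3  # per-pair probability of applying crossover
    p_mutation: float = 0.6  # per-individual probability of applying mutation
    gene_swap_p: float = 0.05  # per-gene swap probability inside crossover
    gene_mut_p: float = 0.05  # per-gene resampling probability inside mutation
    tournament_size: int = 3
    n_groups: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        for name in ("p_crossover", "p_mutation", "gene_swap_p", "gene_mut_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be >= 1")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")


@dataclass
class GenerationStats:
    generation: int
    best: float
    mean: float
    best_ever: float
    n_evaluations: int
    n_cache_hits: int


@dataclass
class GARunRecord:
    """Full trace of one evolutionary run."""

    generations: list[GenerationStats] = field(default_factory=list)
    best_chromosome: np.ndarray | None = None
    best_fitness: float = MIN_FITNESS
    best_report: FitnessReport | None = None
    n_evaluations: int = 0
    n_cache_hits: int = 0

    @property
    def best_ever_trace(self) -> list[float]:
        return [g.best_ever for g in self.generations]


def init_population(n: int, params: GAParams, rng: np.random.Generator) -> list[np.ndarray]:
    """Random initial population: genes i.i.d. uniform on {1..g}."""
    if n < 1:
        raise ValueError("need at least one sub-data set")
    return [rng.integers(1, params.n_groups + 1, size=n) for _ in range(params.population_size)]


def uniform_crossover(
    a: np.ndarray, b: np.ndarray, gene_swap_p: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Swap each position between the two parents with probability gene_swap_p."""
    if len(a) != len(b):
        raise ValueError("chromosome length mismatch")
    swap = rng.random(len(a)) < gene_swap_p
    c1, c2 = a.copy(), b.copy()
    c1[swap], c2[swap] = b[swap], a[swap]
    return c1, c2


def uniform_mutation(c: np.ndarray, gene_mut_p: float, g: int, rng: np.random.Generator) -> np.ndarray:
    """Resample each gene uniformly on {1..g} with probability gene_mut_p.

    Resampling may redraw the current value, so the effective per-gene flip
    rate is gene_mut_p * (1 - 1/g).
    """
    out = c.copy()
    hit = rng.random(len(c)) < gene_mut_p
    out[hit] = rng.integers(1, g + 1, size=int(hit.sum()))
    return out


def tournament_select(
    pop: Sequence[np.ndarray], fitnesses: Sequence[float], k: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw k individuals with replacement; return the fittest (first drawn on ties)."""
    if not pop:
        raise ValueError("empty population")
    idx = rng.integers(0, len(pop), size=k)
    best = idx[0]
    for i in idx[1:]:
        if fitnesses[i] > fitnesses[best]:
            best = i
    return pop[best]


def canonical_form(c: np.ndarray) -> np.ndarray:
    """Relabel groups in order of first appearance (label symmetry quotient)."""
    out = np.empty_like(c)
    mapping: dict[int, int] = {}
    for i, gene in enumerate(c):
        gene = int(gene)
        if gene not in mapping:
            mapping[gene] = len(mapping) + 1
        out[i] = mapping[gene]
    return out


class GroupEvaluator:
    """Scores chromosomes against a pool of reduced sub-data sets.

    Each distinct group (set of member subsets) is scaled, merged and scored
    once; each distinct partition (canonical chromosome) is scored once.  The
    half-set split seed of a group is derived from the run seed and the group
    membership, so a group's statistics do not depend on the chromosome that
    proposed it (and label permutations cannot change fitness).
    """

    def __init__(
        self,
        pool: Sequence[SubDataset],
        weights: FitnessWeights,
        scheme: ShellScheme,
        scaling_model: str = "scale",
        seed: int = 0,
        with_completeness: bool = True,
    ):
        self.pool = list(pool)
        self.weights = weights
        self.scheme = scheme
        self.scaling_model = scaling_model
        self.seed = int(seed)
        self.with_completeness = with_completeness
        self._group_cache: dict[tuple[int, ...], GroupScore] = {}
        self._fitness_cache: dict[bytes, FitnessReport] = {}
        self.n_evaluations = 0
        self.n_cache_hits = 0

    def _half_split_seed(self, members: tuple[int, ...]) -> int:
        digest = zlib.crc32(np.asarray(members, dtype=np.int64).tobytes())
        return (self.seed * 2654435761 + digest) % (2**31)

    def score_members(self, members: tuple[int, ...]) -> GroupScore:
        """Score the merging group formed by the given pool indices."""
        members = tuple(sorted(int(m) for m in members))
        if members in self._group_cache:
            return self._group_cache[members]
        group = [self.pool[m] for m in members]
        try:
            scales = scale_group(group, model=self.scaling_model)
            merged = merge_group(group, scales, rng_seed=self._half_split_seed(members))
            stats = compute_stats(
                merged,
                self.scheme,
                group[0].space_group_number,
                with_completeness=self.with_completeness,
            )
            gs = score_group(stats, self.weights)
            gs.stats = stats
        except Exception:
            logger.exception("evaluation failed for group %s; scored as sentinel", members)
            gs = GroupScore(group_id=0, score=MIN_FITNESS, empty=True)
        self._group_cache[members] = gs
        return gs

    def evaluate(self, chromosome: np.ndarray) -> FitnessReport:
        key = canonical_form(chromosome).tobytes()
        if key in self._fitness_cache:
            self.n_cache_hits += 1
            return self._fitness_cache[key]
        self.n_evaluations += 1
        groups: list[GroupScore] = []
        for gid in sorted(set(int(x) for x in chromosome)):
            members = tuple(int(i) for i in np.flatnonzero(chromosome == gid))
            gs = self.score_members(members)
            gs = GroupScore(
                group_id=gid,
                score=gs.score,
                terms=gs.terms,
                contributions=gs.contributions,
                empty=gs.empty,
                stats=gs.stats,
            )
            groups.append(gs)
        report = score_individual(groups, self.weights)
        self._fitness_cache[key] = report
        return report

    def __call__(self, chromosome: np.ndarray) -> float:
        return self.evaluate(chromosome).fitness


def evolve(
    pool: Sequence[SubDataset],
    params: GAParams,
    evaluator: Callable[[np.ndarray], float],
    callback: Callable[[GenerationStats], None] | None = None,
) -> GARunRecord:
    """Run the generational loop and return the full run trace.

    ``evaluator`` maps a chromosome to a fitness (typically a
    :class:`GroupEvaluator`).  Fully deterministic for a fixed
    ``params.seed`` and serial evaluation.
    """
    n = len(pool)
    ss = np.random.SeedSequence(params.seed)
    rng_init, rng_ops = (np.random.default_rng(s) for s in ss.spawn(2))

    record = GARunRecord()

    def _eval(c: np.ndarray) -> float:
        try:
            return float(evaluator(c))
        except Exception:
            logger.exception("evaluator failed; assigning sentinel fitness")
            return MIN_FITNESS

    pop = init_population(n, params, rng_init)
    fits = [_eval(c) for c in pop]

    def _update_hof() -> None:
        i = int(np.argmax(fits))
        if fits[i] > record.best_fitness:
            record.best_fitness = fits[i]
            record.best_chromosome = pop[i].copy()

    def _snapshot(gen: int) -> None:
        _update_hof()
        ev = getattr(evaluator, "n_evaluations", 0)
        ch = getattr(evaluator, "n_cache_hits", 0)
        gs = GenerationStats(
            generation=gen,
            best=float(np.max(fits)),
            mean=float(np.mean(fits)),
            best_ever=record.best_fitness,
            n_evaluations=ev,
            n_cache_hits=ch,
        )
        record.generations.append(gs)
        if callback is not None:
            callback(gs)

    _snapshot(0)
    for gen in range(1, params.generations + 1):
        offspring = [tournament_select(pop, fits, params.tournament_size, rng_ops).copy() for _ in pop]
        off_fits = [None] * len(offspring)
        # mark untouched clones as already evaluated
        parent_fits = {c.tobytes(): f for c, f in zip(pop, fits)}
        for i in range(len(offspring)):
            off_fits[i] = parent_fits.get(offspring[i].tobytes())
        for i in range(1, len(offspring), 2):
            if rng_ops.random() < params.p_crossover:
                offspring[i - 1], offspring[i] = uniform_crossover(
                    offspring[i - 1], offspring[i], params.gene_swap_p, rng_ops
                )
                off_fits[i - 1] = off_fits[i] = None
        for i in range(len(offspring)):
            if rng_ops.random() < params.p_mutation:
                offspring[i] = uniform_mutation(offspring[i], params.gene_mut_p, params.n_groups, rng_ops)
                off_fits[i] = None
        for i in range(len(offspring)):
            if off_fits[i] is None:
                off_fits[i] = _eval(offspring[i])
        pop, fits = offspring, off_fits
        _snapshot(gen)

    if record.best_chromosome is not None and hasattr(evaluator, "evaluate"):
        record.best_report = evaluator.evaluate(record.best_chromosome)
    record.n_evaluations = getattr(evaluator, "n_evaluations", 0)
    record.n_cache_hits = getattr(evaluator, "n_cache_hits", 0)
    return record
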