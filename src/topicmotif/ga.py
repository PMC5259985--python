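"""The evolutionary loop.

Elitist pairwise selection (random pairs, the lower-perplexity member of
each pair survives), classic one-point crossover over shuffled instance
arrays, and a shift mutation that slides a random subset of a solution's
k-mers by at most one word length.  Fitness values are cached on
individuals and survivors are never re-evaluated, so the best perplexity is
non-increasing across generations; the incumbent best individual is exempt
from mutation to keep that guarantee strict.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import postprocess as _postprocess
from .kmer import (
    GAParams,
    Individual,
    KmerInstance,
    init_population,
)
from .seqio import SequenceSet
from .topicmodel import fitness

logger = logging.getLogger(__name__)

__all__ = [
    "GAParams",
    "Individual",
    "GAHistory",
    "select",
    "crossover",
    "mutate",
    "evaluate_population",
    "run",
    "MotifFinder",
]


@dataclass
class GAHistory:
    """Per-generation trace: (generation, best, median, population size)."""

    generations: list[tuple[int, float, float, int]] = field(default_factory=list)

    def best_series(self) -> list[float]:
        return [g[1] for g in self.generations]

    def population_sizes(self) -> list[int]:
        return [g[3] for g in self.generations]


def evaluate_population(
    population: list[Individual],
    seqs: SequenceSet,
    params: GAParams,
    rng: np.random.Generator,
) -> None:
    for ind in population:
        fitness(ind, seqs, params, rng)


def select(
    population: list[Individual], rng: np.random.Generator
) -> list[Individual]:
    """Elitist pairwise selection: N/2 survivors.

    Individuals are paired uniformly at random without replacement; the
    lower-perplexity member of each pair survives (ties keep the pair's
    first member).  All fitnesses must already be evaluated.
    """
    N = len(population)
    if N % 2 != 0:
        raise ValueError("population size must be even")
    for ind in population:
        if ind.fitness is None:
            raise ValueError("select() requires an evaluated population")
    order = rng.permutation(N)
    survivors = []
    for i in range(0, N, 2):
        a = population[int(order[i])]
        b = population[int(order[i + 1])]
        survivors.append(a if a.fitness <= b.fitness else b)
    return survivors


def crossover(
    parent_a: Individual, parent_b: Individual, rng: np.random.Generator
) -> tuple[Individual, Individual]:
    """Classic one-point crossover over shuffled instance arrays.

    Each parent's instance list is shuffled first; a crossover index x is
    drawn uniformly in [1, n-1]; children swap the tails.  With n < 2 the
    children are (permuted) copies of the parents.  Children carry no
    cached fitness.
    """
    n = len(parent_a.instances)
    if len(parent_b.instances) != n:
        raise ValueError("parents must carry the same number of instances")
    a = [parent_a.instances[int(i)] for i in rng.permutation(n)]
    b = [parent_b.instances[int(i)] for i in rng.permutation(n)]
    if n < 2:
        return Individual(a), Individual(b)
    x = int(rng.integers(1, n))
    return Individual(a[:x] + b[x:]), Individual(b[:x] + a[x:])


def mutate(
    individual: Individual,
    seqs: SequenceSet,
    params: GAParams,
    rng: np.random.Generator,
) -> Individual:
    """Shift mutation.

    With probability ``mutation_rate`` the individual mutates: a subset of
    its instances (size uniform in [1, n]) each has its position shifted by
    a non-zero offset drawn uniformly from [-k, k], clamped to the sequence
    bounds, and its word re-read at the new position.  The cached fitness of
    a mutated individual is invalidated.
    """
    n = len(individual.instances)
    if n == 0 or rng.random() >= params.mutation_rate:
        return individual
    size = int(rng.integers(1, n + 1))
    which = set(int(i) for i in rng.choice(n, size=size, replace=False))
    new_instances: list[KmerInstance] = []
    for idx, inst in enumerate(individual.instances):
        if idx not in which:
            new_instances.append(inst)
            continue
        k = len(inst.word)
        delta = int(rng.integers(-k, k + 1))
        while delta == 0:
            delta = int(rng.integers(-k, k + 1))
        seq = seqs.sequence(inst.doc_index)
        pos = min(max(inst.pos + delta, 0), len(seq) - k)
        new_instances.append(KmerInstance(inst.doc_index, pos, seq[pos : pos + k]))
    return Individual(new_instances)


def _sort_key(ind: Individual) -> float:
    return ind.fitness if ind.fitness is not None else float("inf")


def run(
    seqs: SequenceSet,
    params: GAParams,
    rng: np.random.Generator | None = None,
    history: GAHistory | None = None,
) -> list[Individual]:
    """Full GA run; returns solutions sorted by perplexity (ascending),
    truncated to ``params.max_solutions``.

    Reproducible end-to-end from ``params.seed`` when no generator is
    passed.  Pass a :class:`GAHistory` to capture the per-generation trace.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    population = init_population(seqs, params, rng)
    for gen in range(params.generations + 1):
        evaluate_population(population, seqs, params, rng)
        fits = [ind.fitness for ind in population]
        finite = [f for f in fits if f != float("inf")]
        best = min(fits)
        med = statistics.median(fits) if fits else float("nan")
        if history is not None:
            history.generations.append((gen, best, med, len(population)))
        logger.info(
            "generation %d: best=%.4g median=%.4g (finite %d/%d)",
            gen, best, med, len(finite), len(fits),
        )
        if gen == params.generations:
            break
        survivors = select(population, rng)
        need = params.N - len(survivors)
        children: list[Individual] = []
        while len(children) < need:
            ia, ib = rng.choice(len(survivors), size=2, replace=False)
            c1, c2 = crossover(survivors[int(ia)], survivors[int(ib)], rng)
            children.append(c1)
            if len(children) < need:
                children.append(c2)
        population = survivors + children
        # elitism: the incumbent best never mutates, so the best cached
        # perplexity cannot increase between generations
        best_idx = min(
            (i for i, ind in enumerate(population) if ind.fitness is not None),
            key=lambda i: population[i].fitness,
            default=None,
        )
        population = [
            ind if i == best_idx else mutate(ind, seqs, params, rng)
            for i, ind in enumerate(population)
        ]
    return sorted(population, key=_sort_key)[: params.max_solutions]


class MotifFinder(BaseEstimator):
    """De novo motif finder: GA over overrepresented k-mer sets with
    correlated-topic-model held-out perplexity as the fitness.

    ``fit`` accepts a :class:`~topicmotif.seqio.SequenceSet` or a list of
    DNA strings.  After fitting, ``solutions_`` holds the top GA solutions
    (ascending perplexity), ``motifs_`` the motifs derived from the CTM
    topics of each solution that passes the perplexity confidence filter
    (all solutions, if the filter is disabled), and ``history_`` the
    per-generation fitness trace.
    """

    def __init__(
        self,
        k_min: int = 6,
        k_max: int = 30,
        c_min: int = 1,
        population_size: int = 50,
        words_per_individual: int = 1000,
        generations: int = 90,
        mutation_rate: float = 0.1,
        max_solutions: int = 10,
        n_topics: int = 3,
        mismatch_fraction: float = 0.25,
        perplexity_threshold: float = 100.0,
        confidence_filter: bool = True,
        random_state: int = 0,
    ):
        self.k_min = k_min
        self.k_max = k_max
        self.c_min = c_min
        self.population_size = population_size
        self.words_per_individual = words_per_individual
        self.generations = generations
        self.mutation_rate = mutation_rate
        self.max_solutions = max_solutions
        self.n_topics = n_topics
        self.mismatch_fraction = mismatch_fraction
        self.perplexity_threshold = perplexity_threshold
        self.confidence_filter = confidence_filter
        self.random_state = random_state

    def _params(self) -> GAParams:
        return GAParams(
            k_min=self.k_min,
            k_max=self.k_max,
            c_min=self.c_min,
            N=self.population_size,
            n=self.words_per_individual,
            generations=self.generations,
            mutation_rate=self.mutation_rate,
            max_solutions=self.max_solutions,
            K=self.n_topics,
            mismatch_fraction=self.mismatch_fraction,
            perplexity_threshold=self.perplexity_threshold,
            seed=self.random_state,
        )

    @staticmethod
    def _as_sequence_set(X) -> SequenceSet:
        if isinstance(X, SequenceSet):
            return X
        return SequenceSet([(f"seq{i}", str(s).upper()) for i, s in enumerate(X)])

    def fit(self, X, y=None):
        seqs = self._as_sequence_set(X)
        params = self._params()
        history = GAHistory()
        solutions = run(seqs, params, history=history)
        self.seqs_ = seqs
        self.solutions_ = solutions
        self.history_ = history
        self.best_perplexity_ = (
            solutions[0].fitness if solutions else float("inf")
        )
        motifs = []
        self.filter_verdicts_ = []
        for sol in solutions:
            if not sol.instances or sol.fitness == float("inf"):
                continue
            if self.confidence_filter:
                report, perp = _postprocess.perplexity_filter(
                    sol.instances, seqs, params
                )
                self.filter_verdicts_.append((report, perp))
                if not report:
                    continue
            motifs.extend(_postprocess.topics_to_motifs(sol, seqs, params))
        for rank, motif in enumerate(motifs, 1):
            motif.rank = rank
        self.motifs_ = motifs
        return self
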