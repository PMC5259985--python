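"""Mismatch-tolerant k-mer counting and population initialization.

A candidate word ``w`` drawn at a random position is accepted into an
individual when it is overrepresented in its sequence of origin relative to
a shuffled version of itself: ``c - c_s >= c_min``, where ``c`` counts
windows within the mismatch budget of ``w`` and ``c_s`` the same for one
random letter-shuffle ``w_s``.  The mismatch budget is ``floor(f * k)`` with
``f`` defaulting to 0.25 (k=4 -> 1, k=8 -> 2).  Windows containing N never
count as occurrences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .seqio import N_CODE, SequenceSet, encode


class InitializationError(RuntimeError):
    """Raised when rejection sampling cannot fill an individual."""


@dataclass(frozen=True)
class KmerInstance:
    """One candidate word: its document of origin, position and letters."""

    doc_index: int
    pos: int
    word: str

    def __len__(self) -> int:
        return len(self.word)


@dataclass
class Individual:
    """A GA solution: an ordered list of k-mer instances plus cached fitness.

    ``fitness`` is the held-out perplexity of the correlated topic model
    built from this instance set (lower is better); ``None`` means
    not-yet-evaluated.  Any change to the instance list must invalidate it.
    """

    instances: list[KmerInstance]
    fitness: float | None = None

    def invalidate(self) -> None:
        self.fitness = None

    def copy(self) -> "Individual":
        return Individual(list(self.instances), self.fitness)

    @property
    def words(self) -> list[str]:
        return [inst.word for inst in self.instances]


@dataclass
class GAParams:
    """Run parameters.

    Defaults mirror the published run configuration: motif width 6-30,
    population 50, 90 generations, 1000 words per individual, at most 10
    solutions, mutation rate 0.1, perplexity threshold 100.
    """

    k_min: int = 6
    k_max: int = 30
    c_min: int = 1
    N: int = 50
    n: int = 1000
    generations: int = 90
    mutation_rate: float = 0.1
    max_solutions: int = 10
    K: int = 3
    mismatch_fraction: float = 0.25
    perplexity_threshold: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.k_min <= self.k_max):
            raise ValueError("require 1 <= k_min <= k_max")
        if self.N < 2 or self.N % 2 != 0:
            raise ValueError("population size N must be even and >= 2")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.c_min < 1:
            raise ValueError("c_min must be >= 1")
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if not (0.0 <= self.mismatch_fraction < 1.0):
            raise ValueError("mismatch_fraction must be in [0, 1)")


def mismatch_budget(k: int, mismatch_fraction: float = 0.25) -> int:
    """Allowed Hamming distance for a length-k word: floor(f * k)."""
    return math.floor(mismatch_fraction * k)


def count_occurrences(word, sequence, mismatch_fraction: float = 0.25) -> int:
    """Count windows of ``sequence`` within the mismatch budget of ``word``.

    All windows are scanned, overlaps included.  Windows containing N are
    excluded; a word containing N (or longer than the sequence) has zero
    occurrences.  ``word`` and ``sequence`` may be strings or pre-encoded
    uint8 arrays.
    """
    w = encode(word) if isinstance(word, str) else np.asarray(word)
    s = encode(sequence) if isinstance(sequence, str) else np.asarray(sequence)
    k = w.size
    if k == 0 or k > s.size or (w == N_CODE).any():
        return 0
    windows = sliding_window_view(s, k)
    mismatches = (windows != w).sum(axis=1)
    has_n = (windows == N_CODE).any(axis=1)
    budget = mismatch_budget(k, mismatch_fraction)
    return int(((mismatches <= budget) & ~has_n).sum())


def shuffle_word(word: str, rng: np.random.Generator) -> str:
    """Uniform random permutation of the letters of ``word``."""
    letters = list(word)
    rng.shuffle(letters)
    return "".join(letters)


_MAX_ATTEMPTS_PER_WORD = 10_000


def init_individual(
    seqs: SequenceSet, params: GAParams, rng: np.random.Generator
) -> Individual:
    """Draw one individual by bounded rejection sampling.

    Repeats until ``params.n`` words have passed the shuffle-control
    overrepresentation test ``c - c_s >= c_min``; after
    ``10000 * n`` failed draws an :class:`InitializationError` is raised so a
    pathological input (e.g. shuffle-invariant homopolymers) fails cleanly
    instead of hanging.
    """
    if params.n == 0:
        return Individual([])
    D = len(seqs)
    budget = _MAX_ATTEMPTS_PER_WORD * params.n
    instances: list[KmerInstance] = []
    attempts = 0
    while len(instances) < params.n:
        if attempts >= budget:
            raise InitializationError(
                f"could not draw {params.n} overrepresented k-mers within "
                f"{budget} attempts (c_min={params.c_min}, "
                f"k=[{params.k_min},{params.k_max}])"
            )
        attempts += 1
        k = int(rng.integers(params.k_min, params.k_max + 1))
        d = int(rng.integers(D))
        enc = seqs.encoded(d)
        if enc.size < k:
            continue
        p = int(rng.integers(0, enc.size - k + 1))
        w_enc = enc[p : p + k]
        if (w_enc == N_CODE).any():
            continue
        c = count_occurrences(w_enc, enc, params.mismatch_fraction)
        word = seqs.sequence(d)[p : p + k]
        w_s = shuffle_word(word, rng)
        c_s = count_occurrences(w_s, enc, params.mismatch_fraction)
        if c - c_s >= params.c_min:
            instances.append(KmerInstance(d, p, word))
    return Individual(instances)


def init_population(
    seqs: SequenceSet, params: GAParams, rng: np.random.Generator
) -> list[Individual]:
    """Exactly ``params.N`` independently drawn individuals."""
    return [init_individual(seqs, params, rng) for _ in range(params.N)]
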