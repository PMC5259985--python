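"""Turning GA solutions into reported motifs, and the confidence filter.

A solution's CTM is refitted on its full document-term matrix; every
vocabulary word goes to its highest-probability topic, and each non-empty
topic becomes one motif carrying the solution's instances of its words.
Motifs within a solution are ranked by mean per-column information content
of their position weight matrix (the field's usual motif-quality score).

The perplexity filter is a generic confidence gate for ANY candidate
instance set (not only this package's GA): instances are clustered by
Hamming distance, cluster consensus words form a small vocabulary, a CTM is
fitted, and the motif is reported only when the held-out perplexity falls
below a threshold (default 100).
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .kmer import GAParams, Individual, KmerInstance, mismatch_budget
from .seqio import SequenceSet
from .topicmodel import (
    DegenerateMatrixError,
    build_dtm,
    build_dtm_from_words,
    fit_ctm,
    perplexity,
    split_dtm,
)

_BASES = "ACGT"


@dataclass
class Motif:
    """A reported motif: ranked instances, consensus, and PWM."""

    rank: int
    instances: list[KmerInstance]
    consensus: str
    pwm: np.ndarray  # (4, L) column-stochastic, rows A, C, G, T
    perplexity: float
    info_content: float = field(default=0.0)

    @property
    def length(self) -> int:
        return self.pwm.shape[1]


def _pwm_from_words(words: list[str]) -> np.ndarray:
    """Column-stochastic 4xL base-frequency matrix (rows A, C, G, T).

    N bases are ignored; a column with no informative base falls back to
    uniform.
    """
    L = len(words[0])
    counts = np.zeros((4, L))
    for w in words:
        for i, b in enumerate(w):
            j = _BASES.find(b)
            if j >= 0:
                counts[j, i] += 1
    col = counts.sum(axis=0)
    counts[:, col == 0] = 0.25
    col = counts.sum(axis=0)
    return counts / col


def _consensus_from_pwm(pwm: np.ndarray) -> str:
    # argmax per column; ties resolve alphabetically because A < C < G < T
    return "".join(_BASES[int(j)] for j in pwm.argmax(axis=0))


def _mean_info_content(pwm: np.ndarray) -> float:
    """Mean per-column information content in bits (0 = uniform, 2 = fixed)."""
    p = np.where(pwm > 0, pwm, 1.0)
    entropy = -(pwm * np.log2(p)).sum(axis=0)
    return float((2.0 - entropy).mean())


def _modal_length(instances: list[KmerInstance]) -> int:
    lengths = Counter(len(i.word) for i in instances)
    top = max(lengths.values())
    return min(L for L, c in lengths.items() if c == top)  # ties -> shortest


def consensus_word(words: list[str]) -> str:
    """Per-position majority consensus of same-length words."""
    return _consensus_from_pwm(_pwm_from_words(words))


def topics_to_motifs(
    solution: Individual, seqs: SequenceSet, params: GAParams
) -> list[Motif]:
    """Refit the CTM on the solution's full DTM and return one motif per
    non-empty topic.

    Vocabulary words are assigned to their argmax topic; a motif's PWM is
    built from its instances of the modal length (off-length instances stay
    in the instance list but are excluded from the PWM).  The union of the
    motifs' instance lists is exactly the solution's instance list.  Motifs
    are ranked by mean PWM information content, descending.
    """
    if not solution.instances:
        return []
    dtm = build_dtm(solution.instances, seqs, params.mismatch_fraction)
    K_eff = min(params.K, dtm.V)
    model = fit_ctm(dtm, K_eff, seed=params.seed)
    word_topic = {
        w: int(model.beta[:, j].argmax()) for j, w in enumerate(dtm.vocab)
    }
    by_topic: dict[int, list[KmerInstance]] = defaultdict(list)
    for inst in solution.instances:
        by_topic[word_topic[inst.word]].append(inst)

    sol_perp = solution.fitness if solution.fitness is not None else math.nan
    motifs: list[Motif] = []
    for _, instances in sorted(by_topic.items()):
        L = _modal_length(instances)
        words = [i.word for i in instances if len(i.word) == L]
        pwm = _pwm_from_words(words)
        motifs.append(
            Motif(
                rank=0,
                instances=instances,
                consensus=_consensus_from_pwm(pwm),
                pwm=pwm,
                perplexity=sol_perp,
                info_content=_mean_info_content(pwm),
            )
        )
    motifs.sort(key=lambda m: -m.info_content)
    for rank, m in enumerate(motifs, 1):
        m.rank = rank
    return motifs


def cluster_by_hamming(
    instances: list[KmerInstance], max_dist: int
) -> list[list[KmerInstance]]:
    """Single-linkage clusters of instances under Hamming distance.

    Instances are first grouped by word length (distance is undefined
    across lengths); within a length group, two instances are linked when
    their words differ in at most ``max_dist`` positions.  Returns disjoint
    clusters covering every instance.
    """
    by_len: dict[int, list[KmerInstance]] = defaultdict(list)
    for inst in instances:
        by_len[len(inst.word)].append(inst)

    clusters: list[list[KmerInstance]] = []
    for _, group in sorted(by_len.items()):
        parent = list(range(len(group)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(group)):
            wi = group[i].word
            for j in range(i + 1, len(group)):
                wj = group[j].word
                dist = sum(a != b for a, b in zip(wi, wj))
                if dist <= max_dist:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        members: dict[int, list[KmerInstance]] = defaultdict(list)
        for i, inst in enumerate(group):
            members[find(i)].append(inst)
        clusters.extend(members[r] for r in sorted(members))
    return clusters


def perplexity_filter(
    candidate_instances: list[KmerInstance],
    seqs: SequenceSet,
    params: GAParams,
) -> tuple[bool, float]:
    """Confidence gate: report a candidate motif only when a CTM built from
    its clustered instances has held-out perplexity below the threshold.

    Works for instance sets from any motif finder.  Clustering radius per
    word length k is the mismatch budget floor(0.25 * k); each cluster is
    represented by its consensus word.  Degenerate inputs (empty set,
    all-zero matrix, empty split) are rejected with perplexity +inf.
    """
    if not candidate_instances:
        return False, math.inf
    clusters = cluster_by_hamming_by_budget(
        candidate_instances, params.mismatch_fraction
    )
    representatives = [
        consensus_word([i.word for i in cluster]) for cluster in clusters
    ]
    try:
        dtm = build_dtm_from_words(
            representatives, seqs, params.mismatch_fraction
        )
    except DegenerateMatrixError:
        return False, math.inf
    train, test = split_dtm(dtm)
    if train.total == 0 or test.total == 0:
        return False, math.inf
    K_eff = min(params.K, dtm.V)
    model = fit_ctm(train, K_eff, seed=params.seed)
    perp = perplexity(model, test)
    return perp < params.perplexity_threshold, perp


def cluster_by_hamming_by_budget(
    instances: list[KmerInstance], mismatch_fraction: float = 0.25
) -> list[list[KmerInstance]]:
    """Per-length clustering with radius floor(mismatch_fraction * k)."""
    by_len: dict[int, list[KmerInstance]] = defaultdict(list)
    for inst in instances:
        by_len[len(inst.word)].append(inst)
    clusters: list[list[KmerInstance]] = []
    for k, group in sorted(by_len.items()):
        clusters.extend(
            cluster_by_hamming(group, mismatch_budget(k, mismatch_fraction))
        )
    return clusters
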