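"""Planted-motif dataset generator.

Produces sequence sets with known implanted motif instances — the ground
truth every test in this package scores against.  Backgrounds are either
uniform i.i.d. over A/C/G/T or a first-order Markov chain (a preset
GC-skewed transition table is provided); each planted instance carries an
exact, configurable number of substitutions and instances are distributed
over random sequences at non-overlapping random positions, with no
guarantee of one occurrence per sequence.  ``instances_total = 0`` yields a
pure-background negative control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import SequenceSet, SiteAnnotation

_BASES = "ACGT"

#: First-order transition table biased toward G/C runs (rows/cols A,C,G,T).
GC_SKEWED_TABLE = np.array(
    [
        [0.30, 0.25, 0.30, 0.15],
        [0.15, 0.35, 0.35, 0.15],
        [0.15, 0.35, 0.35, 0.15],
        [0.15, 0.30, 0.25, 0.30],
    ]
)


@dataclass
class PlantSpec:
    """Generation parameters for one planted-motif dataset.

    Defaults describe the small benchmark-like condition used throughout
    the test suite: six 200-bp uniform-background sequences carrying twelve
    copies of an 8-mer, each copy with exactly one substitution.
    """

    motif: str = "TGACGTCA"
    num_sequences: int = 6
    seq_length: int = 200
    instances_total: int = 12
    mutations_per_instance: int = 1
    background: str = "uniform"  # "uniform" | "markov"
    transition: np.ndarray = field(default_factory=lambda: GC_SKEWED_TABLE)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.instances_total < 0:
            raise ValueError("instances_total must be >= 0")
        if not (0 <= self.mutations_per_instance <= len(self.motif)):
            raise ValueError("mutations_per_instance must be in [0, len(motif)]")
        if self.seq_length < len(self.motif):
            raise ValueError("seq_length must be >= len(motif)")
        if set(self.motif) - set(_BASES):
            raise ValueError("motif must be over A/C/G/T")
        if self.background not in ("uniform", "markov"):
            raise ValueError("background must be 'uniform' or 'markov'")
        t = np.asarray(self.transition, dtype=float)
        if t.shape != (4, 4) or not np.allclose(t.sum(axis=1), 1.0):
            raise ValueError("transition must be a 4x4 row-stochastic table")
        self.transition = t


def _background_sequence(spec: PlantSpec, rng: np.random.Generator) -> str:
    L = spec.seq_length
    if spec.background == "uniform":
        return "".join(_BASES[i] for i in rng.integers(0, 4, size=L))
    out = np.empty(L, dtype=np.int64)
    out[0] = rng.integers(0, 4)
    for i in range(1, L):
        out[i] = rng.choice(4, p=spec.transition[out[i - 1]])
    return "".join(_BASES[i] for i in out)


def _mutated_motif(spec: PlantSpec, rng: np.random.Generator) -> str:
    word = list(spec.motif)
    positions = rng.choice(len(word), size=spec.mutations_per_instance, replace=False)
    for p in positions:
        choices = [b for b in _BASES if b != word[p]]
        word[p] = choices[int(rng.integers(3))]
    return "".join(word)


_PLACEMENT_RETRIES = 1000


def generate(spec: PlantSpec) -> tuple[SequenceSet, list[SiteAnnotation]]:
    """Generate a planted-motif dataset with exact ground truth.

    Returns the sequences and one annotation per planted instance
    (0-based half-open, '+' strand, carrying the implanted string).
    Raises ``RuntimeError`` if non-overlapping placement fails after
    bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    seqs = [list(_background_sequence(spec, rng)) for _ in range(spec.num_sequences)]
    m = len(spec.motif)
    occupied: dict[int, list[tuple[int, int]]] = {
        d: [] for d in range(spec.num_sequences)
    }
    annotations: list[SiteAnnotation] = []
    for _ in range(spec.instances_total):
        placed = False
        for _ in range(_PLACEMENT_RETRIES):
            d = int(rng.integers(spec.num_sequences))
            p = int(rng.integers(0, spec.seq_length - m + 1))
            if any(p < e and s < p + m for s, e in occupied[d]):
                continue
            word = _mutated_motif(spec, rng)
            seqs[d][p : p + m] = list(word)
            occupied[d].append((p, p + m))
            annotations.append(SiteAnnotation(f"seq{d}", p, p + m, "+", word))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place {spec.instances_total} non-overlapping "
                f"instances after {_PLACEMENT_RETRIES} retries each"
            )
    records = [(f"seq{d}", "".join(s)) for d, s in enumerate(seqs)]
    annotations.sort(key=lambda a: (a.seq_id, a.start))
    return SequenceSet(records), annotations


def shuffle_dataset(seqs: SequenceSet, seed: int = 0) -> SequenceSet:
    """Letter-shuffle each sequence independently (mononucleotide
    composition preserved per sequence; any planted signal destroyed)."""
    rng = np.random.default_rng(seed)
    records = []
    for sid, seq in seqs:
        letters = list(seq)
        rng.shuffle(letters)
        records.append((sid, "".join(letters)))
    return SequenceSet(records)
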