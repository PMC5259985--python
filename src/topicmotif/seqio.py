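"""Sequence and binding-site I/O, plus the shared data model.

Coordinates are 0-based, half-open everywhere inside the package; the motif
report additionally carries 1-based inclusive columns for human reading.
Sequences are restricted to the {A, C, G, T, N} alphabet and are case-folded
to upper case on read.  Record order is preserved and defines the document
index ``d`` used by the topic model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGTN"
_CODE = {b: i for i, b in enumerate(ALPHABET)}
N_CODE = _CODE["N"]


class FastaParseError(ValueError):
    """Raised for malformed or invalid FASTA input."""


class SiteValidationError(ValueError):
    """Raised for an invalid site-annotation record."""


def encode(sequence: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A=0, C=1, G=2, T=3, N=4)."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    if (out == 255).any():
        bad = sequence[int(np.argmax(out == 255))]
        raise ValueError(f"illegal base {bad!r}; alphabet is {ALPHABET}")
    return out


@dataclass
class SequenceSet:
    """An ordered collection of named DNA sequences (the "documents")."""

    records: list[tuple[str, str]]
    _encoded: dict[int, np.ndarray] = field(
        default_factory=dict, repr=False, compare=False
    )
    _index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for sid, seq in self.records:
            if not sid:
                raise FastaParseError("empty sequence id")
            if sid in seen:
                raise FastaParseError(f"duplicate sequence id {sid!r}")
            seen.add(sid)
            if not seq:
                raise FastaParseError(f"empty sequence for id {sid!r}")
            bad = set(seq) - set(ALPHABET)
            if bad:
                raise FastaParseError(
                    f"sequence {sid!r} contains illegal characters {sorted(bad)}"
                )
        self._index = {sid: d for d, (sid, _) in enumerate(self.records)}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.records)

    def __getitem__(self, d: int) -> tuple[str, str]:
        return self.records[d]

    @property
    def ids(self) -> list[str]:
        return [sid for sid, _ in self.records]

    def sequence(self, d: int) -> str:
        return self.records[d][1]

    def length(self, d: int) -> int:
        return len(self.records[d][1])

    def index_of(self, seq_id: str) -> int:
        try:
            return self._index[seq_id]
        except KeyError:
            raise KeyError(f"unknown sequence id {seq_id!r}") from None

    def encoded(self, d: int) -> np.ndarray:
        """Integer-encoded sequence ``d`` (cached)."""
        arr = self._encoded.get(d)
        if arr is None:
            arr = encode(self.records[d][1])
            self._encoded[d] = arr
        return arr


@dataclass(frozen=True)
class SiteAnnotation:
    """One annotated (known or predicted) site, 0-based half-open."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"
    site: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise SiteValidationError(
                f"invalid interval [{self.start}, {self.end}) for {self.seq_id!r}"
            )
        if self.strand not in ("+", "-"):
            raise SiteValidationError(f"invalid strand {self.strand!r}")
        if self.site and len(self.site) != self.end - self.start:
            raise SiteValidationError(
                f"site string length {len(self.site)} != interval length "
                f"{self.end - self.start} for {self.seq_id!r}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def validate_against(self, seqs: SequenceSet) -> None:
        d = seqs.index_of(self.seq_id)
        if self.end > seqs.length(d):
            raise SiteValidationError(
                f"site [{self.start}, {self.end}) exceeds length "
                f"{seqs.length(d)} of sequence {self.seq_id!r}"
            )


def read_fasta(path) -> SequenceSet:
    """Read a multi-record FASTA file into a :class:`SequenceSet`.

    Sequences are upper-cased; record order is preserved.  Malformed input
    (no records, data before the first header, duplicate ids, illegal
    characters) raises :class:`FastaParseError` naming the offending line.
    """
    header_lines: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">"):
                header_lines.append(lineno)
            elif line.strip() and not header_lines:
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before first '>' header"
                )
    if not header_lines:
        raise FastaParseError(f"{path}: line 1: no FASTA records found")

    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for lineno, rec in zip(header_lines, _BioSeqIO.parse(str(path), "fasta")):
        sid = rec.id
        if not sid:
            raise FastaParseError(f"{path}: line {lineno}: empty header")
        if sid in seen:
            raise FastaParseError(f"{path}: line {lineno}: duplicate id {sid!r}")
        seen.add(sid)
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaParseError(f"{path}: line {lineno}: empty sequence {sid!r}")
        bad = set(seq) - set(ALPHABET)
        if bad:
            raise FastaParseError(
                f"{path}: line {lineno}: illegal characters {sorted(bad)} in {sid!r}"
            )
        records.append((sid, seq))
    return SequenceSet(records)


def write_fasta(seqs: SequenceSet, path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in seqs.records
    ]
    _BioSeqIO.write(recs, str(path), "fasta")


def read_sites(path) -> list[SiteAnnotation]:
    """Read 5-column tab-delimited site annotations.

    Columns: seq_id, start (0-based), end (exclusive), strand, site string
    (may be empty).  Extra columns (e.g. the report's 1-based pair) are
    ignored; lines starting with '#' and blank lines are skipped.  Unknown
    seq_ids are tolerated here and rejected at scoring time.
    """
    out: list[SiteAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise SiteValidationError(
                    f"{path}: line {lineno}: expected >=4 tab-separated columns"
                )
            sid, start_s, end_s, strand = fields[:4]
            site = fields[4] if len(fields) > 4 else ""
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise SiteValidationError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            try:
                out.append(SiteAnnotation(sid, start, end, strand, site))
            except SiteValidationError as exc:
                raise SiteValidationError(f"{path}: line {lineno}: {exc}") from None
    return out


def write_sites(sites, path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.seq_id}\t{s.start}\t{s.end}\t{s.strand}\t{s.site}\n")


def write_motif_report(motifs, seqs: SequenceSet, path) -> None:
    """Write one block per motif: a consensus comment line, then one
    annotation row per instance.

    Rows carry the 0-based half-open pair and, for human reading, a 1-based
    inclusive pair.  Blocks appear in motif-rank order; rows are sorted by
    (seq_id, start).
    """
    with open(path, "w") as fh:
        fh.write("# topicmotif motif report\n")
        fh.write("# columns: seq_id\tstart0\tend0\tstrand\tsite\tstart1\tend1\n")
        for motif in motifs:
            fh.write(
                f"# motif {motif.rank}\tconsensus={motif.consensus}"
                f"\tinstances={len(motif.instances)}"
                f"\tperplexity={motif.perplexity:.6g}\n"
            )
            rows = sorted(
                motif.instances, key=lambda i: (seqs.ids[i.doc_index], i.pos)
            )
            for inst in rows:
                sid = seqs.ids[inst.doc_index]
                start, end = inst.pos, inst.pos + len(inst.word)
                fh.write(
                    f"{sid}\t{start}\t{end}\t+\t{inst.word}\t{start + 1}\t{end}\n"
                )
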