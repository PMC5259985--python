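"""Nucleotide- and site-level scoring of motif predictions.

Follows the Tompa-style benchmark convention: per-position confusion counts
over every sequence (nTP/nFP/nTN/nFN), site counts under the
quarter-overlap rule (a predicted site matches a known site when it covers
at least ceil(len(known)/4) of its positions), eight derived statistics,
and the benchmark's sum-then-score combination across datasets (counts are
summed first, the statistics computed once on the sums).

The nucleotide correlation coefficient is

    nCC = (nTP*nTN - nFN*nFP) / sqrt((nTP+nFN)(nTN+nFP)(nTP+nFP)(nTN+nFN))

i.e. Matthews' correlation; a published variant with '+' in the numerator
is a typographical error (it would not lie in [-1, 1]).  Ratios of the form
0/0 are reported as NaN and excluded from any averaging by the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .seqio import SequenceSet, SiteAnnotation, SiteValidationError


@dataclass
class AssessmentCounts:
    """Raw confusion counts; n* at nucleotide level, s* at site level."""

    nTP: int = 0
    nFP: int = 0
    nTN: int = 0
    nFN: int = 0
    sTP: int = 0
    sFP: int = 0
    sFN: int = 0

    def __add__(self, other: "AssessmentCounts") -> "AssessmentCounts":
        return AssessmentCounts(
            **{
                f.name: getattr(self, f.name) + getattr(other, f.name)
                for f in fields(self)
            }
        )


@dataclass
class AssessmentScores:
    nSn: float
    nPPV: float
    nSp: float
    nPC: float
    nCC: float
    sSn: float
    sPPV: float
    sASP: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _coverage(sites: list[SiteAnnotation], length: int) -> np.ndarray:
    cov = np.zeros(length, dtype=bool)
    for s in sites:
        cov[s.start : s.end] = True
    return cov


def _group_by_seq(sites) -> dict[str, list[SiteAnnotation]]:
    out: dict[str, list[SiteAnnotation]] = {}
    for s in sites:
        out.setdefault(s.seq_id, []).append(s)
    return out


def nucleotide_counts(
    predicted: list[SiteAnnotation],
    known: list[SiteAnnotation],
    seqs: SequenceSet,
) -> AssessmentCounts:
    """Per-position confusion counts over every position of every sequence.

    Overlapping annotations are merged into coverage sets first, so a
    position is counted once regardless of how many sites span it.
    Annotations referencing unknown sequences or exceeding bounds raise.
    """
    for s in list(predicted) + list(known):
        s.validate_against(seqs)
    pred_by = _group_by_seq(predicted)
    known_by = _group_by_seq(known)
    counts = AssessmentCounts()
    for sid, seq in seqs:
        L = len(seq)
        p = _coverage(pred_by.get(sid, []), L)
        k = _coverage(known_by.get(sid, []), L)
        counts.nTP += int((p & k).sum())
        counts.nFP += int((p & ~k).sum())
        counts.nFN += int((~p & k).sum())
        counts.nTN += int((~p & ~k).sum())
    return counts


def _overlap(a: SiteAnnotation, b: SiteAnnotation) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def quarter_threshold(known_site: SiteAnnotation) -> int:
    """Minimum overlap for a match: one quarter of the known site's
    length, rounded up."""
    return -(-len(known_site) // 4)


def site_counts(
    predicted: list[SiteAnnotation], known: list[SiteAnnotation]
) -> AssessmentCounts:
    """Site-level confusion counts under the quarter-overlap rule.

    Known sites are matched one-to-one to predicted sites greedily by
    largest overlap (ties: leftmost known site, then leftmost predicted).
    sTP counts matched known sites, sFN unmatched known sites, and sFP the
    predicted sites whose overlap with every known site falls below that
    site's quarter threshold.
    """
    pred_by = _group_by_seq(predicted)
    known_by = _group_by_seq(known)
    counts = AssessmentCounts()
    for sid in sorted(set(pred_by) | set(known_by)):
        preds = sorted(pred_by.get(sid, []), key=lambda s: (s.start, s.end))
        knowns = sorted(known_by.get(sid, []), key=lambda s: (s.start, s.end))
        pairs = []
        for ki, k in enumerate(knowns):
            thr = quarter_threshold(k)
            for pi, p in enumerate(preds):
                ov = _overlap(p, k)
                if ov >= thr:
                    pairs.append((-ov, k.start, p.start, ki, pi))
        pairs.sort()
        used_k: set[int] = set()
        used_p: set[int] = set()
        matched = 0
        for _, _, _, ki, pi in pairs:
            if ki in used_k or pi in used_p:
                continue
            used_k.add(ki)
            used_p.add(pi)
            matched += 1
        counts.sTP += matched
        counts.sFN += len(knowns) - matched
        counts.sFP += sum(
            1
            for p in preds
            if not any(_overlap(p, k) >= quarter_threshold(k) for k in knowns)
        )
    return counts


def _ratio(num: float, den: float) -> float:
    return num / den if den != 0 else math.nan


def compute_scores(counts: AssessmentCounts) -> AssessmentScores:
    """The eight statistics; 0/0 ratios are NaN."""
    for f in fields(counts):
        if getattr(counts, f.name) < 0:
            raise ValueError(f"negative count {f.name}")
    nTP, nFP, nTN, nFN = counts.nTP, counts.nFP, counts.nTN, counts.nFN
    sTP, sFP, sFN = counts.sTP, counts.sFP, counts.sFN
    denom_cc = (
        (nTP + nFN) * (nTN + nFP) * (nTP + nFP) * (nTN + nFN)
    )
    nCC = (
        (nTP * nTN - nFN * nFP) / math.sqrt(denom_cc)
        if denom_cc > 0
        else math.nan
    )
    sSn = _ratio(sTP, sTP + sFN)
    sPPV = _ratio(sTP, sTP + sFP)
    sASP = (
        (sSn + sPPV) / 2.0
        if not (math.isnan(sSn) or math.isnan(sPPV))
        else math.nan
    )
    return AssessmentScores(
        nSn=_ratio(nTP, nTP + nFN),
        nPPV=_ratio(nTP, nTP + nFP),
        nSp=_ratio(nTN, nTN + nFP),
        nPC=_ratio(nTP, nTP + nFN + nFP),
        nCC=nCC,
        sSn=sSn,
        sPPV=sPPV,
        sASP=sASP,
    )


def combine_counts(counts_list: list[AssessmentCounts]) -> AssessmentCounts:
    if not counts_list:
        raise ValueError("empty counts list")
    total = AssessmentCounts()
    for c in counts_list:
        total = total + c
    return total


def combine(counts_list: list[AssessmentCounts]) -> AssessmentScores:
    """Benchmark-style combination: sum the raw counts over datasets, then
    compute the eight statistics once on the summed counts."""
    return compute_scores(combine_counts(counts_list))


def assess(
    predicted: list[SiteAnnotation],
    known: list[SiteAnnotation],
    seqs: SequenceSet,
) -> tuple[AssessmentCounts, AssessmentScores]:
    """Convenience wrapper: both count levels and the eight statistics."""
    counts = nucleotide_counts(predicted, known, seqs)
    sc = site_counts(predicted, known)
    counts.sTP, counts.sFP, counts.sFN = sc.sTP, sc.sFP, sc.sFN
    return counts, compute_scores(counts)
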