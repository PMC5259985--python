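import math

import numpy as np
import pytest

from topicmotif import (
    AssessmentCounts,
    SequenceSet,
    SiteAnnotation,
    SiteValidationError,
    combine,
    combine_counts,
    compute_scores,
    nucleotide_counts,
    site_counts,
)


def brute_force_nucleotide(predicted, known, seqs):
    """Independent per-position set-comparison oracle."""
    tp = fp = tn = fn = 0
    for sid, seq in seqs:
        pred = {i for s in predicted if s.seq_id == sid for i in range(s.start, s.end)}
        true = {i for s in known if s.seq_id == sid for i in range(s.start, s.end)}
        for i in range(len(seq)):
            if i in pred and i in true:
                tp += 1
            elif i in pred:
                fp += 1
            elif i in true:
                fn += 1
            else:
                tn += 1
    return tp, fp, tn, fn


@pytest.fixture
def toy():
    seqs = SequenceSet([("s1", "A" * 100)])
    known = [SiteAnnotation("s1", 10, 20)]
    predicted = [SiteAnnotation("s1", 15, 25)]
    return seqs, known, predicted


def test_toy_nucleotide_counts(toy):
    seqs, known, predicted = toy
    c = nucleotide_counts(predicted, known, seqs)
    assert (c.nTP, c.nFP, c.nFN, c.nTN) == (5, 5, 5, 85)


def test_toy_scores(toy):
    seqs, known, predicted = toy
    s = compute_scores(nucleotide_counts(predicted, known, seqs))
    assert s.nSn == pytest.approx(0.5)
    assert s.nPPV == pytest.approx(0.5)
    assert s.nPC == pytest.approx(1 / 3)
    assert s.nSp == pytest.approx(85 / 90)
    assert s.nCC == pytest.approx((5 * 85 - 5 * 5) / math.sqrt(10 * 90 * 10 * 90))


def test_exact_predictions_have_no_errors(toy):
    seqs, known, _ = toy
    c = nucleotide_counts(known, known, seqs)
    assert c.nFP == 0 and c.nFN == 0
    s = site_counts(known, known)
    assert s.sFP == 0 and s.sFN == 0 and s.sTP == 1


def test_no_predictions_defaults_to_zero_sensitivity(toy):
    seqs, known, _ = toy
    c = nucleotide_counts([], known, seqs)
    assert (c.nTP, c.nFP, c.nFN, c.nTN) == (0, 0, 10, 90)
    sc = site_counts([], known)
    c.sTP, c.sFP, c.sFN = sc.sTP, sc.sFP, sc.sFN
    s = compute_scores(c)
    assert s.nSn == 0 and s.sSn == 0
    assert math.isnan(s.nPPV) and math.isnan(s.sPPV)


def test_overlapping_annotations_merge_to_coverage(toy):
    seqs, known, _ = toy
    doubled = known + [SiteAnnotation("s1", 12, 18)]
    assert nucleotide_counts(doubled, known, seqs) == nucleotide_counts(
        known, known, seqs
    )


def test_nucleotide_counts_match_brute_force_oracle(rng):
    seqs = SequenceSet(
        [(f"s{i}", "ACGT" * int(rng.integers(10, 30))) for i in range(4)]
    )
    for _ in range(200):
        def random_sites(m):
            out = []
            for _ in range(m):
                d = int(rng.integers(4))
                L = seqs.length(d)
                a = int(rng.integers(0, L - 2))
                b = int(rng.integers(a + 1, min(L, a + 15) + 1))
                out.append(SiteAnnotation(f"s{d}", a, b))
            return out

        pred, known = random_sites(int(rng.integers(0, 6))), random_sites(
            int(rng.integers(0, 6))
        )
        c = nucleotide_counts(pred, known, seqs)
        assert (c.nTP, c.nFP, c.nTN, c.nFN) == tuple(
            brute_force_nucleotide(pred, known, seqs)[i] for i in (0, 1, 2, 3)
        )
        total = sum(seqs.length(d) for d in range(4))
        assert c.nTP + c.nFP + c.nTN + c.nFN == total


def test_annotation_out_of_bounds_raises():
    seqs = SequenceSet([("s1", "ACGTACGT")])
    with pytest.raises(SiteValidationError):
        nucleotide_counts([SiteAnnotation("s1", 4, 20)], [], seqs)
    with pytest.raises(KeyError):
        nucleotide_counts([SiteAnnotation("sX", 0, 4)], [], seqs)


# ------------------------------------------------------------- site level


def test_quarter_overlap_boundary():
    known = [SiteAnnotation("s1", 10, 20)]  # length 10 -> threshold ceil(10/4)=3
    miss = site_counts([SiteAnnotation("s1", 18, 28)], known)  # overlap 2
    hit = site_counts([SiteAnnotation("s1", 17, 27)], known)  # overlap 3
    assert (miss.sTP, miss.sFN, miss.sFP) == (0, 1, 1)
    assert (hit.sTP, hit.sFN, hit.sFP) == (1, 0, 0)


def test_greedy_matching_prefers_largest_overlap_then_leftmost():
    known = [SiteAnnotation("s1", 0, 8), SiteAnnotation("s1", 20, 28)]
    # one prediction overlapping the second known site more
    pred = [SiteAnnotation("s1", 6, 26)]
    c = site_counts(pred, known)
    assert c.sTP == 1 and c.sFN == 1 and c.sFP == 0
    # tie in overlap -> leftmost known site matched first
    pred = [SiteAnnotation("s1", 4, 24)]
    c = site_counts(pred, known)
    assert c.sTP == 1 and c.sFN == 1


def test_prediction_overlapping_matched_site_is_not_false_positive():
    known = [SiteAnnotation("s1", 10, 20)]
    pred = [SiteAnnotation("s1", 10, 20), SiteAnnotation("s1", 12, 22)]
    c = site_counts(pred, known)
    # only one prediction can claim the site, but the second still meets the
    # quarter rule and therefore is not counted as a false positive
    assert (c.sTP, c.sFN, c.sFP) == (1, 0, 0)


# ----------------------------------------------------------------- scores


def test_perfect_counts_score_one():
    s = compute_scores(AssessmentCounts(nTP=40, nTN=60, sTP=5))
    assert all(v == 1.0 for v in s.as_dict().values())


def test_no_true_positive_sign_behavior():
    s = compute_scores(AssessmentCounts(nTP=0, nFP=10, nFN=10, nTN=80, sFP=1, sFN=1))
    assert s.nSn == 0 and s.nPPV == 0 and s.nCC <= 0


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        compute_scores(AssessmentCounts(nTP=-1))


# ---------------------------------------------------------------- combine


def test_combine_single_dataset_identity():
    c = AssessmentCounts(5, 5, 85, 5, 2, 1, 1)
    assert combine([c]) == compute_scores(c)


def test_combine_requires_nonempty_list():
    with pytest.raises(ValueError):
        combine([])


def test_combine_equals_unpartitioned_scores(rng):
    seqs = SequenceSet([(f"s{i}", "ACGT" * 30) for i in range(6)])
    def random_sites(m):
        out = []
        for _ in range(m):
            d = int(rng.integers(6))
            a = int(rng.integers(0, 110))
            out.append(SiteAnnotation(f"s{d}", a, a + int(rng.integers(1, 11))))
        return out

    pred, known = random_sites(12), random_sites(12)
    whole = nucleotide_counts(pred, known, seqs)
    sc = site_counts(pred, known)
    whole.sTP, whole.sFP, whole.sFN = sc.sTP, sc.sFP, sc.sFN

    for _ in range(50):
        assignment = rng.integers(0, 3, size=6)
        parts = []
        for g in range(3):
            ids = {f"s{i}" for i in range(6) if assignment[i] == g}
            if not ids:
                continue
            sub = SequenceSet([r for r in seqs.records if r[0] in ids])
            p = [s for s in pred if s.seq_id in ids]
            k = [s for s in known if s.seq_id in ids]
            c = nucleotide_counts(p, k, sub)
            s = site_counts(p, k)
            c.sTP, c.sFP, c.sFN = s.sTP, s.sFP, s.sFN
            parts.append(c)
        assert combine_counts(parts) == whole
        assert combine(parts) == compute_scores(whole)
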