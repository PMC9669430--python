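"""Filtering rules, ORF/Fickett scoring and positional classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lncflow as lf
from lncflow.models import GeneModel, GenomeAnnotation, TranscriptModel

from .oracles import brute_longest_orf


def _annotation():
    """One coding gene on chr1:+ with exons 101-200, 301-400, 501-600."""
    t = TranscriptModel("ref.t1", "chr1", "+", ((101, 200), (301, 400), (501, 600)),
                        "refg")
    return GenomeAnnotation([GeneModel("refg", "chr1", "+", 101, 600, "coding", [t])])


# ---------------------------------------------------------------------------
# filter_candidates


def test_length_filter_is_strictly_below_200():
    ref = _annotation()
    short = TranscriptModel("c199", "chr1", "+", ((10_000, 10_198),))
    exact = TranscriptModel("c200", "chr1", "+", ((20_000, 20_199),))
    retained, table = lf.filter_candidates([short, exact], ref)
    assert [t.transcript_id for t in retained] == ["c200"]
    row = table.set_index("transcript_id")
    assert row.loc["c199", "reason"] == "short"
    assert bool(row.loc["c200", "retained"])


def test_known_mrna_removed_by_exact_intron_chain():
    ref = _annotation()
    same_introns = TranscriptModel(
        "cand1", "chr1", "+", ((90, 200), (301, 400), (501, 650)), None
    )  # different ends, same intron chain -> removed
    shifted = TranscriptModel(
        "cand2", "chr1", "+", ((101, 200), (301, 401), (502, 600)), None
    )  # intron boundaries differ -> retained
    opposite = TranscriptModel(
        "cand3", "chr1", "-", ((101, 200), (301, 400), (501, 600)), None
    )  # strand differs -> retained
    retained, table = lf.filter_candidates([same_introns, shifted, opposite], ref)
    reasons = dict(zip(table["transcript_id"], table["reason"]))
    assert reasons["cand1"] == "known_mrna"
    assert {t.transcript_id for t in retained} == {"cand2", "cand3"}


def test_single_exon_known_mrna_needs_exact_interval():
    t = TranscriptModel("ref.t1", "chr1", "+", ((101, 600),), "refg")
    ref = GenomeAnnotation([GeneModel("refg", "chr1", "+", 101, 600, "coding", [t])])
    dup = TranscriptModel("dup", "chr1", "+", ((101, 600),))
    near = TranscriptModel("near", "chr1", "+", ((102, 600),))
    retained, table = lf.filter_candidates([dup, near], ref)
    assert [t.transcript_id for t in retained] == ["near"]
    assert table.set_index("transcript_id").loc["dup", "reason"] == "known_mrna"


def test_unknown_chromosome_warns_and_retains_with_flag():
    ref = _annotation()
    odd = TranscriptModel("odd", "chrUn", "+", ((1_000, 1_400),))
    with pytest.warns(UserWarning, match="chrUn"):
        retained, table = lf.filter_candidates([odd], ref)
    assert [t.transcript_id for t in retained] == ["odd"]
    assert table.loc[0, "flag"] == "unknown_chrom"


def test_every_candidate_retained_or_has_exactly_one_reason(dataset):
    retained, table = lf.filter_candidates(
        dataset["candidates"], dataset["annotation"]
    )
    assert len(table) == len(dataset["candidates"])
    removed = table[~table["retained"]]
    assert removed["reason"].isin(["known_mrna", "short"]).all()
    assert (table[table["retained"]]["reason"] == "").all()
    assert len(retained) + len(removed) == len(table)


# ---------------------------------------------------------------------------
# longest_orf


@pytest.mark.parametrize(
    "seq, expected",
    [
        ("ATGAAATAG", (1, 9, 0)),
        ("CCCCCC", (0, 0, None)),
        ("ATGTAA", (1, 6, 0)),
        ("AATGAAATAA", (2, 9, 1)),  # frame 1 ORF
        ("ATGAAA", (0, 0, None)),  # no stop, no complete ORF
    ],
)
def test_longest_orf_examples(seq, expected):
    assert lf.longest_orf(seq) == expected


def test_longest_orf_rejects_bad_alphabet():
    with pytest.raises(ValueError):
        lf.longest_orf("ATGNNNTAA")


def test_longest_orf_matches_exhaustive_enumeration(rng):
    for _ in range(1000):
        n = int(rng.integers(3, 300))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        start, length, _ = lf.longest_orf(seq)
        assert (start, length) == brute_longest_orf(seq)


# ---------------------------------------------------------------------------
# fickett_score


def test_fickett_poly_a_value_from_published_tables():
    """A 300-nt poly-A: every positional count equal (parameter 100/101),
    A-content 1, C/G/T content 0; summing the table entries by hand gives
    0.26*0.22 + 0.18*0.23 + 0.31*0.08 + 0.33*0.09
    + 0.11*0.28 + 0.12*0.31 + 0.15*0.29 + 0.14*0.58 = 0.3458."""
    assert lf.fickett_score("A" * 300) == pytest.approx(0.3458)


def test_fickett_is_deterministic_and_bounded(rng):
    seq = "".join(rng.choice(list("ACGT"), size=400))
    s = lf.fickett_score(seq)
    assert s == lf.fickett_score(seq)
    assert 0.26 <= s <= 1.82


def test_random_sequences_score_in_noncoding_region(rng):
    """Mean TESTCODE of uniform-random sequence sits below the coding
    threshold of 0.95 (in the classic no-opinion/noncoding range)."""
    scores = [
        lf.fickett_score("".join(rng.choice(list("ACGT"), size=300)))
        for _ in range(300)
    ]
    assert np.mean(scores) < 0.80


# ---------------------------------------------------------------------------
# coding_potential


def test_contaminants_coding_and_planted_lncrnas_noncoding(dataset):
    truth, seqs = dataset["truth"], dataset["seqs"]
    for tid, cat in truth.candidate_category.items():
        if cat == "coding_contaminant":
            assert lf.coding_potential(seqs[tid]).label == "coding"
        elif cat == "lncrna":
            score = lf.coding_potential(seqs[tid])
            assert score.label == "noncoding"
            assert score.longest_orf_nt < 100


def test_coding_call_via_long_orf_threshold():
    orf = "ATG" + "AAA" * 120 + "TAA"  # 366-nt ORF
    seq = orf + "C" * 100
    assert lf.coding_potential(seq).label == "coding"
    assert lf.coding_potential(seq, orf_min=400).label == "noncoding"


# ---------------------------------------------------------------------------
# classification


def test_intronic_same_strand_inside_intron():
    ref = _annotation()
    t = TranscriptModel("x", "chr1", "+", ((210, 290),))
    assert lf.classify_lncrna(t, ref) == "intronic"


def test_intergenic_when_no_overlap():
    ref = _annotation()
    t = TranscriptModel("x", "chr1", "+", ((5_000, 5_400),))
    assert lf.classify_lncrna(t, ref) == "intergenic"


def test_exonic_beats_antisense_beats_intronic_precedence():
    ref = _annotation()
    sense = TranscriptModel("s", "chr1", "+", ((150, 320),))
    anti = TranscriptModel("a", "chr1", "-", ((150, 320),))
    assert lf.classify_lncrna(sense, ref) == "exonic_sense_overlap"
    assert lf.classify_lncrna(anti, ref) == "antisense"


@settings(max_examples=50, deadline=None)
@given(start=st.integers(1, 2_000), length=st.integers(1, 800),
       strand=st.sampled_from("+-"))
def test_classification_is_total_and_exclusive(start, length, strand):
    ref = _annotation()
    t = TranscriptModel("x", "chr1", strand, ((start, start + length - 1),))
    assert lf.classify_lncrna(t, ref) in lf.models.LNCRNA_CLASSES


def test_full_dataset_class_labels_recover_truth(dataset):
    truth = dataset["truth"]
    retained, _ = lf.filter_candidates(dataset["candidates"], dataset["annotation"])
    noncoding = [
        t for t in retained
        if lf.coding_potential(dataset["seqs"][t.transcript_id]).label == "noncoding"
    ]
    classified = lf.classify_all(noncoding, dataset["annotation"])
    predicted = dict(zip(classified["transcript_id"], classified["class"]))
    assert predicted == truth.class_labels
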