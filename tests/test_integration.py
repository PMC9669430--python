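"""Cis-target windows, Smith-Waterman alignment, precursor scan, networks."""

import numpy as np
import pytest
from Bio import Align

import lncflow as lf
from lncflow.models import CisPair, GeneModel, GenomeAnnotation, TranscriptModel

from .oracles import brute_cis_pairs, brute_local_align_score


def _ref(genes):
    return GenomeAnnotation([
        GeneModel(gid, chrom, strand, start, end, "coding",
                  [TranscriptModel(f"{gid}.t", chrom, strand, ((start, end),), gid)])
        for gid, chrom, strand, start, end in genes
    ])


def _lnc(tid, chrom, start, end, strand="+"):
    return TranscriptModel(tid, chrom, strand, ((start, end),))


# ---------------------------------------------------------------------------
# predict_cis_targets


def test_gap_arithmetic_example():
    ref = _ref([("g", "chr1", "+", 50_000, 60_000)])
    pairs = lf.predict_cis_targets([_lnc("l", "chr1", 1_000, 2_000)], ref)
    assert len(pairs) == 1
    assert pairs[0].gap_bp == 47_999
    assert pairs[0].relation == "upstream"


def test_window_boundary_is_strict():
    ref = _ref([("g", "chr1", "+", 200_001, 210_000)])
    at_window = [_lnc("l", "chr1", 1, 100_000)]     # gap exactly 100,000
    inside = [_lnc("l2", "chr1", 1, 100_001)]       # gap 99,999
    assert lf.predict_cis_targets(at_window, ref) == []
    got = lf.predict_cis_targets(inside, ref)
    assert [(p.gene_id, p.gap_bp) for p in got] == [("g", 99_999)]


def test_overlap_gives_gap_zero_relation_overlap():
    ref = _ref([("g", "chr1", "+", 1_000, 5_000)])
    pairs = lf.predict_cis_targets([_lnc("l", "chr1", 4_500, 6_000)], ref)
    assert pairs == [CisPair("l", "g", 0, "overlap")]


def test_relation_respects_gene_strand():
    ref = _ref([("g", "chr1", "-", 50_000, 60_000)])
    left = lf.predict_cis_targets([_lnc("l", "chr1", 1_000, 2_000)], ref)
    right = lf.predict_cis_targets([_lnc("r", "chr1", 70_000, 71_000)], ref)
    assert left[0].relation == "downstream"
    assert right[0].relation == "upstream"


def test_cis_pairs_match_brute_force_on_random_loci(rng):
    chroms = ["chr1", "chr2"]
    genes, lncs = [], []
    for i in range(250):
        c = chroms[int(rng.integers(2))]
        s = int(rng.integers(1, 2_000_000))
        genes.append((f"g{i}", c, "+-"[int(rng.integers(2))], s,
                      s + int(rng.integers(100, 5_000))))
    for i in range(250):
        c = chroms[int(rng.integers(2))]
        s = int(rng.integers(1, 2_000_000))
        lncs.append(_lnc(f"l{i}", c, s, s + int(rng.integers(100, 3_000))))
    ref = _ref(genes)
    window = 50_000
    got = {
        (p.lncrna_id, p.gene_id, p.gap_bp)
        for p in lf.predict_cis_targets(lncs, ref, window=window)
    }
    expected = brute_cis_pairs(
        {t.transcript_id: (t.chrom, t.start, t.end) for t in lncs},
        {gid: (c, s, e) for gid, c, _, s, e in genes},
        window,
    )
    assert got == expected


# ---------------------------------------------------------------------------
# local_align


def test_identity_alignment_score():
    hit = lf.local_align("ACGT", "ACGT")
    assert hit.score == 8.0
    assert hit.identity == 1.0 and hit.coverage == 1.0


def test_single_match_best():
    assert lf.local_align("ACGT", "TTTT").score == 2.0


def test_alignment_rejects_bad_alphabet_and_empty():
    with pytest.raises(ValueError):
        lf.local_align("ACGX", "ACGT")
    with pytest.raises(ValueError):
        lf.local_align("", "ACGT")


def test_score_symmetric_under_sequence_exchange(rng):
    for _ in range(50):
        a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 30))))
        b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 30))))
        assert lf.local_align(a, b).score == lf.local_align(b, a).score


def test_scores_match_exhaustive_recursion_on_tiny_pairs(rng):
    for _ in range(100):
        a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 8))))
        b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 8))))
        assert lf.local_align(a, b).score == brute_local_align_score(a, b)


def test_scores_match_biopython_on_random_pairs(rng):
    aligner = Align.PairwiseAligner(
        mode="local", match_score=2, mismatch_score=-1,
        open_gap_score=-2, extend_gap_score=-2,
    )
    for _ in range(200):
        a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 50))))
        b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 50))))
        assert lf.local_align(a, b).score == aligner.score(a, b)


# ---------------------------------------------------------------------------
# precursor_scan


def test_embedded_precursor_hits_with_full_identity(dataset):
    truth, seqs = dataset["truth"], dataset["seqs"]
    host, pid, _ = truth.precursor_embeddings[0]
    hits, n = lf.precursor_scan({host: seqs[host]}, truth.precursor_seqs)
    assert n == 1
    best = hits[0]
    assert best.identity == 1.0 and best.coverage == 1.0


def test_shuffled_database_yields_zero_hits(dataset, rng):
    truth, seqs = dataset["truth"], dataset["seqs"]
    shuffled = {
        pid: "".join(rng.permutation(list(s)))
        for pid, s in truth.precursor_seqs.items()
    }
    del_seqs = {h: seqs[h] for h, _, _ in truth.precursor_embeddings}
    hits, n = lf.precursor_scan(del_seqs, shuffled)
    assert hits == [] and n == 0


def test_empty_database_returns_empty():
    hits, n = lf.precursor_scan({"a": "ACGTACGT"}, {})
    assert hits == [] and n == 0


def test_threshold_validation():
    with pytest.raises(ValueError):
        lf.precursor_scan({"a": "ACGT"}, {"p": "ACGT"}, min_identity=0.0)


# ---------------------------------------------------------------------------
# build_core_network


def test_concordant_and_discordant_edges():
    cis = [CisPair("l1", "g1", 10, "upstream"), CisPair("l2", "g2", 0, "overlap"),
           CisPair("l3", "g3", 5, "downstream")]
    conc, disc, summary = lf.build_core_network(
        cis,
        {"l1": "up", "l2": "up", "l3": "up"},
        {"g1": "up", "g2": "down"},  # g3 not a DEM -> no edge
    )
    assert [(e.del_id, e.dem_id) for e in conc] == [("l1", "g1")]
    assert [(e.del_id, e.dem_id) for e in disc] == [("l2", "g2")]
    assert summary["cis_gene_dem_overlap"] == 2
    assert summary["concordant_pairs"] == 1 and summary["discordant_pairs"] == 1


def test_edge_count_at_least_distinct_gene_count(rng):
    """One gene can pair with multiple DELs, never the reverse."""
    cis = [CisPair(f"l{i}", f"g{i % 4}", int(rng.integers(0, 100)), "upstream")
           for i in range(12)]
    conc, disc, summary = lf.build_core_network(
        cis,
        {f"l{i}": "up" for i in range(12)},
        {f"g{j}": ("up" if j % 2 else "down") for j in range(4)},
    )
    assert len(conc) + len(disc) >= summary["cis_gene_dem_overlap"]


def test_graph_export_roundtrip():
    conc, disc, _ = lf.build_core_network(
        [CisPair("l1", "g1", 0, "overlap")], {"l1": "down"}, {"g1": "down"}
    )
    g = lf.integration.edges_to_graph(conc + disc)
    assert g.nodes["l1"]["kind"] == "DEL"
    assert g.edges["l1", "g1"]["concordant"] is True
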