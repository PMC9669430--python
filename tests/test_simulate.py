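"""Generator determinism, planted-structure fidelity and NB count moments."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import lncflow as lf
from lncflow import io as lio


def _file_hashes(d: Path) -> dict[str, str]:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(d.iterdir())
    }


def test_same_seed_gives_byte_identical_files(tmp_path):
    cfg = lf.SimulationConfig(seed=5, n_coding_genes=30, n_lncrna_per_class=2,
                              cis_distance_spec=(5_000,), precursor_embed_count=3)
    lf.write_dataset(cfg, tmp_path / "a")
    lf.write_dataset(cfg, tmp_path / "b")
    assert _file_hashes(tmp_path / "a") == _file_hashes(tmp_path / "b")


def test_empty_gene_config_yields_empty_annotation():
    cfg = lf.SimulationConfig(
        n_coding_genes=0, n_lncrna_per_class=0, cis_distance_spec=(),
        precursor_embed_count=0, n_short_fragments=0, n_coding_contaminants=0,
    )
    annotation, genome, truth = lf.simulate_genome(cfg)
    assert len(annotation) == 0
    assert len(genome) == cfg.n_chromosomes


def test_placement_error_when_genome_too_small():
    cfg = lf.SimulationConfig(n_chromosomes=1, chrom_length=10_000)
    with pytest.raises(lf.simulate.PlacementError):
        lf.simulate_genome(cfg)


@pytest.mark.parametrize(
    "bad",
    [dict(nb_dispersion=0.0), dict(de_fraction=1.5), dict(group_sizes=(0, 3)),
     dict(de_log2fc=-1.0)],
)
def test_invalid_config_rejected(bad):
    with pytest.raises(ValueError):
        lf.SimulationConfig(**bad).validate()


def test_planted_cis_gaps_reproduced_from_emitted_gtf(tmp_path, sim_config):
    """Re-parse the emitted GTFs and recompute every planted gap."""
    paths = lf.write_dataset(sim_config, tmp_path)
    annotation = lio.read_gtf_annotation(paths["reference_gtf"])
    cands = {t.transcript_id: t
             for t in lio.read_gtf_transcripts(paths["assembly_gtf"])}
    truth_cis = lio.read_tsv(paths["truth_cis_tsv"])
    assert set(truth_cis["gap_bp"]) == set(sim_config.cis_distance_spec)
    for row in truth_cis.itertuples():
        lnc, gene = cands[row.lncrna_id], annotation.get(row.gene_id)
        observed = lf.models.interval_gap(lnc.span, gene.span)
        assert observed == row.gap_bp


def test_short_fragment_counts_and_lengths(dataset):
    truth = dataset["truth"]
    frags = [t for t in dataset["candidates"]
             if truth.candidate_category[t.transcript_id] == "short_fragment"]
    assert len(frags) == dataset["config"].n_short_fragments
    assert all(t.length < 200 for t in frags)


def test_intronic_lncrnas_sit_inside_one_host_intron(dataset):
    truth, annotation = dataset["truth"], dataset["annotation"]
    intronic = [t for t in dataset["candidates"]
                if truth.class_labels.get(t.transcript_id) == "intronic"]
    assert intronic
    for t in intronic:
        hosts = [
            tr for g in annotation.genes_on(t.chrom) if g.biotype == "coding"
            for tr in g.transcripts if tr.strand == t.strand
            for (is_, ie) in tr.introns if is_ <= t.start and t.end <= ie
        ]
        assert hosts, f"{t.transcript_id} not inside any same-strand intron"


def test_embedded_precursors_are_verbatim_substrings(tmp_path, sim_config):
    """Substring search on the emitted FASTA files, independent of SimTruth
    coordinates."""
    paths = lf.write_dataset(sim_config, tmp_path)
    cand_seqs = lio.read_fasta(paths["assembly_fasta"])
    precursors = lio.read_fasta(paths["precursor_fasta"])
    emb = lio.read_tsv(paths["truth_precursors_tsv"])
    assert len(emb) == sim_config.precursor_embed_count
    for row in emb.itertuples():
        host = cand_seqs[row.lncrna_id]
        pre = precursors[row.precursor_id]
        assert len(pre) == sim_config.precursor_length
        assert host.find(pre) == row.start - 1


def test_truth_ids_exist_in_emitted_annotation_and_assembly(dataset):
    truth = dataset["truth"]
    cand_ids = {t.transcript_id for t in dataset["candidates"]}
    gene_ids = {g.gene_id for g in dataset["annotation"]}
    assert set(truth.class_labels) <= cand_ids
    for lnc, gene, _ in truth.cis_pairs_planted:
        assert lnc in cand_ids and gene in gene_ids
    assert set(truth.de_features) <= cand_ids | gene_ids


def test_extracted_genome_sequences_match_assembly_fasta(tmp_path, sim_config):
    """Spliced re-extraction from the genome FASTA reproduces the assembly
    FASTA exactly (truth consistency across files)."""
    paths = lf.write_dataset(sim_config, tmp_path)
    cands = lio.read_gtf_transcripts(paths["assembly_gtf"])
    expected = lio.read_fasta(paths["assembly_fasta"])
    extracted = lio.extract_transcript_sequences(cands, paths["genome_fasta"])
    assert extracted == expected


def test_nb_counts_match_negative_binomial_moments():
    """mean ~ m and variance ~ m + a*m^2 over 10,000 draws."""
    m, alpha, n = 100.0, 0.1, 10_000
    cfg = lf.SimulationConfig(seed=3, group_sizes=(n // 2, n // 2),
                              nb_dispersion=alpha)
    feats = pd.DataFrame(
        {"feature_id": ["f1"], "length": [1000], "base_mean": [m]}
    )
    cm = lf.simulate_counts(feats, None, cfg)
    x = cm.counts.loc["f1"].to_numpy(float)
    expected_var = m + alpha * m**2
    assert abs(x.mean() - m) < 3 * np.sqrt(expected_var / n)
    assert abs(x.var() - expected_var) / expected_var < 0.15


def test_planted_log2fc_scales_group_two_mean():
    """log2FC = +2 at base mean 200 gives a group-2 mean near 800."""
    cfg = lf.SimulationConfig(seed=4, group_sizes=(2000, 2000),
                              nb_dispersion=0.05, de_log2fc=2.0)
    truth = lf.SimTruth(de_features={"f1": ("up", 2.0)})
    feats = pd.DataFrame(
        {"feature_id": ["f1"], "length": [1000], "base_mean": [200.0]}
    )
    cm = lf.simulate_counts(feats, truth, cfg)
    by_group = cm.group_samples()
    m1 = cm.counts.loc["f1", by_group["group1"]].mean()
    m2 = cm.counts.loc["f1", by_group["group2"]].mean()
    assert abs(m1 - 200) < 3 * np.sqrt((200 + 0.05 * 200**2) / 2000)
    assert abs(m2 - 800) < 3 * np.sqrt((800 + 0.05 * 800**2) / 2000)


def test_null_config_log_ratios_center_on_zero():
    cfg = lf.SimulationConfig(seed=6, group_sizes=(50, 50), de_fraction=0.0)
    feats = pd.DataFrame(
        {"feature_id": [f"f{i}" for i in range(200)],
         "length": [1000] * 200, "base_mean": [150.0] * 200}
    )
    cm = lf.simulate_counts(feats, None, cfg)
    by_group = cm.group_samples()
    ratios = np.log2(
        cm.counts[by_group["group2"]].mean(axis=1)
        / cm.counts[by_group["group1"]].mean(axis=1)
    )
    assert abs(ratios.mean()) < 0.05
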