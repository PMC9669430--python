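"""File-level orchestration: simulate -> discover -> quantify -> de ->
integrate -> enrich, with TSV intermediates at every stage boundary.

Each stage reads its inputs from disk and writes plain-text outputs under
its own subdirectory of ``outdir``, so any stage can be rerun in isolation
and a rerun with unchanged inputs and seed is byte-identical.  A manifest
of produced files with SHA-256 checksums is written at the end of a full
run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import discovery, enrichment, integration
from . import io as lio
from .differential import call_de, de_summary, de_test
from .expression import CountMatrix, compute_fpkm, expression_summaries, sample_correlation
from .simulate import SimulationConfig, write_dataset

log = logging.getLogger("lncflow")

STAGES = ("simulate", "discover", "quantify", "de", "integrate", "enrich")


@dataclass
class PipelineConfig:
    """Paths and parameters for every stage; defaults run the bundled
    synthetic demo end-to-end."""

    outdir: str = "lncflow_out"
    seed: int = 0
    simulate: bool = True  # generate inputs under <outdir>/sim
    sim: dict = field(default_factory=dict)  # SimulationConfig overrides

    # explicit inputs (used when simulate is off; filled in otherwise)
    reference_gtf: Optional[str] = None
    genome_fasta: Optional[str] = None
    assembly_gtf: Optional[str] = None
    assembly_fasta: Optional[str] = None
    counts_tsv: Optional[str] = None
    groups_tsv: Optional[str] = None
    features_tsv: Optional[str] = None
    precursor_fasta: Optional[str] = None
    gene_sets_gmt: Optional[str] = None

    # stage parameters
    min_len: int = 200
    orf_min: int = 300
    fickett_cut: float = 0.95
    cov_min: float = 0.5
    de_method: str = "t_logfpkm"
    pseudocount: float = 1.0
    fc_cut: float = 2.0
    q_cut: float = 0.05
    window: int = 100_000
    min_identity: float = 0.9
    min_coverage: float = 0.9
    top_k: int = 20

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed, **self.sim)

    def path(self, *parts: str) -> str:
        return os.path.join(self.outdir, *parts)

    def input_paths(self) -> dict[str, Optional[str]]:
        return {
            k: getattr(self, k)
            for k in (
                "reference_gtf", "genome_fasta", "assembly_gtf", "assembly_fasta",
                "counts_tsv", "groups_tsv", "features_tsv", "precursor_fasta",
                "gene_sets_gmt",
            )
        }

    def resolve_inputs(self) -> None:
        """Point unset inputs at the simulate stage's output files."""
        simdir = self.path("sim")
        defaults = {
            "reference_gtf": "reference.gtf", "genome_fasta": "genome.fa",
            "assembly_gtf": "assembly.gtf", "assembly_fasta": "assembly.fa",
            "counts_tsv": "counts.tsv", "groups_tsv": "groups.tsv",
            "features_tsv": "features.tsv", "precursor_fasta": "precursors.fa",
            "gene_sets_gmt": "gene_sets.gmt",
        }
        for key, fname in defaults.items():
            if getattr(self, key) is None:
                setattr(self, key, os.path.join(simdir, fname))


# ---------------------------------------------------------------------------
# validation


def validate_inputs(config: PipelineConfig) -> dict[str, list[str]]:
    """Parse-check every input and cross-check namespaces.

    Returns ``{"errors": [...], "warnings": [...]}``; errors block a run.
    """
    config.resolve_inputs()
    errors: list[str] = []
    warnings_: list[str] = []
    paths = config.input_paths()
    missing = [k for k, p in paths.items() if p is None or not os.path.exists(p)]
    if missing:
        return {"errors": [f"missing input file(s): {missing}"], "warnings": []}

    try:
        reference = lio.read_gtf_annotation(paths["reference_gtf"])
        candidates = lio.read_gtf_transcripts(paths["assembly_gtf"])
        genome = lio.read_fasta(paths["genome_fasta"])
        counts, groups = lio.read_counts(paths["counts_tsv"], paths["groups_tsv"])
        features = lio.read_tsv(paths["features_tsv"])
        lio.read_fasta(paths["precursor_fasta"])
        lio.read_gmt(paths["gene_sets_gmt"])
    except Exception as exc:  # unparseable input is a blocking error
        return {"errors": [f"failed to parse inputs: {exc}"], "warnings": []}

    ref_chroms = {g.chrom for g in reference}
    for chrom in sorted(ref_chroms - set(genome)):
        warnings_.append(f"reference chromosome {chrom} absent from genome FASTA")
    for chrom in sorted({t.chrom for t in candidates} - ref_chroms):
        warnings_.append(f"assembly chromosome {chrom} absent from reference")

    unlabelled = [s for s in counts.columns if s not in groups]
    if unlabelled:
        errors.append(f"samples missing from group sidecar: {unlabelled}")
    if len(set(groups.values())) != 2:
        errors.append("group sidecar must define exactly two groups")
    unknown_features = set(counts.index) - set(features["feature_id"])
    if unknown_features:
        errors.append(
            f"count features missing from features table: "
            f"{sorted(unknown_features)[:5]}"
        )
    return {"errors": errors, "warnings": warnings_}


# ---------------------------------------------------------------------------
# stages


def _write(df: pd.DataFrame, path: str, label: str) -> str:
    os.makedirs(os.path.dirname(path), exist_ok=True)
    lio.write_tsv(df, path)
    log.info("%s: wrote %d rows -> %s", label, len(df), path)
    return path


def stage_simulate(config: PipelineConfig) -> list[str]:
    paths = write_dataset(config.sim_config(), config.path("sim"))
    log.info("simulate: wrote %d files under %s", len(paths), config.path("sim"))
    return sorted(paths.values())


def stage_discover(config: PipelineConfig) -> list[str]:
    config.resolve_inputs()
    reference = lio.read_gtf_annotation(config.reference_gtf)
    candidates = lio.read_gtf_transcripts(config.assembly_gtf)
    seqs = lio.read_fasta(config.assembly_fasta)

    retained, reasons = discovery.filter_candidates(
        candidates, reference, min_len=config.min_len
    )
    scores = {
        t.transcript_id: discovery.coding_potential(
            seqs[t.transcript_id],
            orf_min=config.orf_min,
            fickett_cut=config.fickett_cut,
            cov_min=config.cov_min,
        )
        for t in retained
    }
    noncoding = [t for t in retained if scores[t.transcript_id].label == "noncoding"]
    classified = discovery.classify_all(noncoding, reference)
    lnc_table = classified.assign(
        longest_orf_nt=[scores[i].longest_orf_nt for i in classified["transcript_id"]],
        orf_coverage=[scores[i].orf_coverage for i in classified["transcript_id"]],
        fickett=[scores[i].fickett for i in classified["transcript_id"]],
    )
    coding_table = pd.DataFrame(
        [
            (t.transcript_id, s.longest_orf_nt, s.orf_coverage, s.fickett, s.label)
            for t in retained
            for s in [scores[t.transcript_id]]
        ],
        columns=["transcript_id", "longest_orf_nt", "orf_coverage", "fickett", "label"],
    )
    hists = discovery.structure_histograms(classified)
    out = [
        _write(lnc_table, config.path("discovery", "lncrnas.tsv"), "discover"),
        _write(coding_table, config.path("discovery", "coding_potential.tsv"), "discover"),
        _write(reasons, config.path("discovery", "filter_reasons.tsv"), "discover"),
        _write(discovery.class_summary(classified),
               config.path("discovery", "class_counts.tsv"), "discover"),
        _write(hists["exon_counts"], config.path("discovery", "exon_hist.tsv"),
               "discover"),
        _write(hists["lengths"], config.path("discovery", "length_hist.tsv"),
               "discover"),
    ]
    return out


def _load_counts(config: PipelineConfig) -> CountMatrix:
    counts, groups = lio.read_counts(config.counts_tsv, config.groups_tsv)
    features = lio.read_tsv(config.features_tsv).set_index("feature_id")
    return CountMatrix(
        counts=counts,
        groups=groups,
        lengths=features["length"],
        kinds=features["kind"],
    )


def stage_quantify(config: PipelineConfig) -> list[str]:
    config.resolve_inputs()
    cm = _load_counts(config)
    expr = compute_fpkm(cm)
    corr = sample_correlation(expr)
    summaries = expression_summaries(expr)
    fpkm = expr.fpkm.rename_axis("feature_id").reset_index()
    corr_df = corr.rename_axis("sample_id").reset_index()
    quart = summaries["kind_quartiles"]
    quart_df = (quart.reset_index() if quart is not None
                else pd.DataFrame(columns=["kind", "q25", "median", "q75"]))
    mwu = summaries["mwu"] or {}
    mwu_df = pd.DataFrame([mwu]) if mwu else pd.DataFrame(
        columns=["U", "p_value", "median_mRNA", "median_lncRNA"])
    return [
        _write(fpkm, config.path("expression", "fpkm.tsv"), "quantify"),
        _write(corr_df, config.path("expression", "correlation.tsv"), "quantify"),
        _write(summaries["density"], config.path("expression", "density.tsv"),
               "quantify"),
        _write(quart_df, config.path("expression", "kind_quartiles.tsv"), "quantify"),
        _write(mwu_df, config.path("expression", "kind_comparison.tsv"), "quantify"),
    ]


def stage_de(config: PipelineConfig) -> list[str]:
    config.resolve_inputs()
    cm = _load_counts(config)
    called = call_de(
        de_test(cm, method=config.de_method, pseudocount=config.pseudocount),
        fc_cut=config.fc_cut,
        q_cut=config.q_cut,
    )
    table = called.reset_index()
    summary = de_summary(called, kinds=cm.kinds)
    return [
        _write(table, config.path("de", "de_table.tsv"), "de"),
        _write(summary, config.path("de", "de_summary.tsv"), "de"),
    ]


def _load_calls(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    de_table = lio.read_tsv(config.path("de", "de_table.tsv")).set_index("feature_id")
    lnc = lio.read_tsv(config.path("discovery", "lncrnas.tsv"))
    return de_table, lnc


def stage_integrate(config: PipelineConfig) -> list[str]:
    config.resolve_inputs()
    de_table, lnc = _load_calls(config)
    features = lio.read_tsv(config.features_tsv).set_index("feature_id")
    reference = lio.read_gtf_annotation(config.reference_gtf)
    candidates = {t.transcript_id: t
                  for t in lio.read_gtf_transcripts(config.assembly_gtf)}
    seqs = lio.read_fasta(config.assembly_fasta)

    lnc_ids = [i for i in lnc["transcript_id"] if i in de_table.index]
    del_ids = [i for i in lnc_ids if de_table.loc[i, "direction"] in ("up", "down")]
    dels = [candidates[i] for i in del_ids]

    cis = integration.predict_cis_targets(dels, reference, window=config.window)
    precursors = lio.read_fasta(config.precursor_fasta)
    hits, n_hit_dels = integration.precursor_scan(
        {i: seqs[i] for i in del_ids}, precursors,
        min_identity=config.min_identity, min_coverage=config.min_coverage,
    )

    mrna_ids = features.index[features["kind"] == "mRNA"]
    dem_dirs = de_table.loc[de_table.index.intersection(mrna_ids), "direction"]
    dem_calls = dem_dirs[dem_dirs.isin(["up", "down"])].to_dict()
    del_calls = {i: de_table.loc[i, "direction"] for i in del_ids}
    conc, disc, summary = integration.build_core_network(cis, del_calls, dem_calls)
    summary = dict(summary, precursor_bearing_dels=n_hit_dels, n_dels=len(del_ids),
                   n_dems=len(dem_calls))
    summary_df = pd.DataFrame(sorted(summary.items()), columns=["metric", "value"])
    return [
        _write(integration.cis_pairs_to_frame(cis),
               config.path("integration", "cis_pairs.tsv"), "integrate"),
        _write(integration.hits_to_frame(hits),
               config.path("integration", "precursor_hits.tsv"), "integrate"),
        _write(integration.edges_to_frame(conc + disc),
               config.path("integration", "edges.tsv"), "integrate"),
        _write(summary_df, config.path("integration", "network_summary.tsv"),
               "integrate"),
    ]


def stage_enrich(config: PipelineConfig) -> list[str]:
    config.resolve_inputs()
    de_table, _ = _load_calls(config)
    features = lio.read_tsv(config.features_tsv).set_index("feature_id")
    terms = lio.read_gmt(config.gene_sets_gmt)

    mrna_ids = set(features.index[features["kind"] == "mRNA"])
    background = set(de_table.index) & mrna_ids
    degs = {
        i for i in background
        if de_table.loc[i, "direction"] in ("up", "down")
    }
    deg_enr = enrichment.hypergeom_enrich(degs, background, terms)

    cis_path = config.path("integration", "cis_pairs.tsv")
    cis_genes: set[str] = set()
    if os.path.exists(cis_path):
        cis_df = lio.read_tsv(cis_path)
        if len(cis_df):
            cis_genes = set(cis_df["gene_id"]) & background
    cis_enr = enrichment.hypergeom_enrich(cis_genes, background, terms)
    return [
        _write(deg_enr, config.path("enrichment", "deg_enrichment.tsv"), "enrich"),
        _write(enrichment.top_terms(deg_enr, k=config.top_k),
               config.path("enrichment", "deg_top_terms.tsv"), "enrich"),
        _write(cis_enr, config.path("enrichment", "cis_enrichment.tsv"), "enrich"),
        _write(enrichment.top_terms(cis_enr, k=config.top_k),
               config.path("enrichment", "cis_top_terms.tsv"), "enrich"),
    ]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "discover": stage_discover,
    "quantify": stage_quantify,
    "de": stage_de,
    "integrate": stage_integrate,
    "enrich": stage_enrich,
}


def run_pipeline(
    config: PipelineConfig, stages: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Run the requested stages in dependency order; returns the manifest
    (file, sha256) of everything produced.

    A stage failure aborts the run with the failing stage named.
    """
    if stages is None:
        stages = [s for s in STAGES if s != "simulate" or config.simulate]
    bad = set(stages) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stage(s): {sorted(bad)}")
    stages = [s for s in STAGES if s in set(stages)]

    if "simulate" not in stages:
        report = validate_inputs(config)
        for w in report["warnings"]:
            log.warning("validate: %s", w)
        if report["errors"]:
            raise RuntimeError(f"input validation failed: {report['errors']}")

    produced: list[str] = []
    for stage in stages:
        try:
            produced.extend(_STAGE_FUNCS[stage](config))
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest = pd.DataFrame(
        {
            "file": [os.path.relpath(p, config.outdir) for p in produced],
            "sha256": [_sha256(p) for p in produced],
        }
    ).sort_values("file", kind="mergesort").reset_index(drop=True)
    lio.write_tsv(manifest, config.path("manifest.tsv"))
    return manifest


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
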