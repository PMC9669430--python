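"""Readers and writers for the plain-text formats the pipeline exchanges.

GTF parsing is delegated to :mod:`gffutils`; FASTA handling to Biopython and
:mod:`pyfaidx`; tabular files are pandas TSVs.  All writers emit
deterministic output (sorted, fixed float formatting) so that reruns with
the same seed are byte-identical.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Optional

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyfaidx import Fasta

from .models import GeneModel, GenomeAnnotation, TranscriptModel

# ---------------------------------------------------------------------------
# GTF


def _gtf_attrs(**kwargs: str) -> str:
    return " ".join(f'{k} "{v}";' for k, v in kwargs.items() if v is not None)


def write_gtf_annotation(annotation: GenomeAnnotation, path: str | os.PathLike) -> None:
    """Serialize a gene-level annotation as GTF (gene/transcript/exon rows)."""
    with open(path, "w") as fh:
        for gene in annotation:
            attrs = _gtf_attrs(gene_id=gene.gene_id, gene_biotype=gene.biotype)
            fh.write(
                f"{gene.chrom}\tlncflow\tgene\t{gene.start}\t{gene.end}"
                f"\t.\t{gene.strand}\t.\t{attrs}\n"
            )
            for t in gene.transcripts:
                _write_transcript_rows(fh, t, biotype=gene.biotype)


def write_gtf_transcripts(
    transcripts: Iterable[TranscriptModel], path: str | os.PathLike
) -> None:
    """Serialize bare transcripts (assembly candidates) as GTF."""
    with open(path, "w") as fh:
        for t in transcripts:
            _write_transcript_rows(fh, t)


def _write_transcript_rows(fh, t: TranscriptModel, biotype: Optional[str] = None) -> None:
    attrs = _gtf_attrs(
        gene_id=t.gene_id or t.transcript_id,
        transcript_id=t.transcript_id,
        gene_biotype=biotype,
    )
    fh.write(
        f"{t.chrom}\tlncflow\ttranscript\t{t.start}\t{t.end}\t.\t{t.strand}\t.\t{attrs}\n"
    )
    for start, end in t.exons:
        fh.write(
            f"{t.chrom}\tlncflow\texon\t{start}\t{end}\t.\t{t.strand}\t.\t{attrs}\n"
        )


def _gtf_db(path: str | os.PathLike) -> gffutils.FeatureDB:
    return gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )


def read_gtf_transcripts(path: str | os.PathLike) -> list[TranscriptModel]:
    """Read all transcripts (with exon structure) from a GTF file."""
    db = _gtf_db(path)
    out: list[TranscriptModel] = []
    for t in db.features_of_type("transcript", order_by=("seqid", "start")):
        exons = sorted(
            (e.start, e.end)
            for e in db.children(t, featuretype="exon", order_by="start")
        )
        tid = t.attributes["transcript_id"][0]
        gid = t.attributes.get("gene_id", [None])[0]
        out.append(TranscriptModel(tid, t.seqid, t.strand, tuple(exons), gid))
    return out


def read_gtf_annotation(path: str | os.PathLike) -> GenomeAnnotation:
    """Read a reference GTF into a gene-level annotation.

    ``gene_biotype`` attributes of ``protein_coding``/``coding`` map to
    biotype ``coding``; anything else is ``noncoding``.  Files without gene
    rows fall back to grouping transcripts by ``gene_id``.
    """
    db = _gtf_db(path)
    transcripts = read_gtf_transcripts(path)
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id or t.transcript_id, []).append(t)

    genes: list[GeneModel] = []
    seen = set()
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = g.attributes["gene_id"][0]
        raw = g.attributes.get("gene_biotype", ["coding"])[0]
        biotype = "coding" if raw in ("protein_coding", "coding") else "noncoding"
        genes.append(
            GeneModel(gid, g.seqid, g.strand, g.start, g.end, biotype,
                      by_gene.get(gid, []))
        )
        seen.add(gid)
    for gid, ts in by_gene.items():
        if gid in seen:
            continue
        genes.append(
            GeneModel(gid, ts[0].chrom, ts[0].strand,
                      min(t.start for t in ts), max(t.end for t in ts),
                      "coding", ts)
        )
    return GenomeAnnotation(genes)


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def extract_transcript_sequences(
    transcripts: Iterable[TranscriptModel], genome_fasta: str | os.PathLike
) -> dict[str, str]:
    """Spliced transcript sequences from a genome FASTA (minus strand is
    reverse-complemented)."""
    fa = Fasta(str(genome_fasta))
    out: dict[str, str] = {}
    for t in transcripts:
        parts = [str(fa[t.chrom][s - 1 : e]) for s, e in t.exons]
        seq = "".join(parts).upper()
        if t.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        out[t.transcript_id] = seq
    return out


# ---------------------------------------------------------------------------
# Tables


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_counts(
    counts: pd.DataFrame, groups: Mapping[str, str],
    counts_path: str | os.PathLike, groups_path: str | os.PathLike,
) -> None:
    """Counts TSV (features x samples, index column ``feature_id``) plus a
    sample -> group sidecar."""
    counts.rename_axis("feature_id").to_csv(counts_path, sep="\t")
    pd.DataFrame(
        {"sample_id": list(groups), "group": [groups[s] for s in groups]}
    ).to_csv(groups_path, sep="\t", index=False)


def read_counts(
    counts_path: str | os.PathLike, groups_path: str | os.PathLike
) -> tuple[pd.DataFrame, dict[str, str]]:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    sidecar = pd.read_csv(groups_path, sep="\t")
    groups = dict(zip(sidecar["sample_id"], sidecar["group"]))
    return counts, groups


# ---------------------------------------------------------------------------
# GMT gene sets


def write_gmt(terms: Mapping[str, tuple[str, list[str]]], path: str | os.PathLike) -> None:
    """``terms`` maps term_id -> (description, gene list)."""
    with open(path, "w") as fh:
        for term_id, (desc, genes) in terms.items():
            fh.write("\t".join([term_id, desc, *genes]) + "\n")


def read_gmt(path: str | os.PathLike) -> dict[str, tuple[str, list[str]]]:
    out: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = (parts[1], parts[2:])
    return out
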