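"""Self-contained synthetic dataset generator with recorded ground truth.

Emulates the study design the pipeline targets: two groups of three
biological replicates (two coat colours, three animals each), a small
multi-chromosome genome carrying coding genes and planted noncoding loci,
an assembly containing known-mRNA re-discoveries, sub-200-nt fragments,
coding contaminants and true lncRNAs of every positional class, negative
binomial counts with planted fold changes, cis pairs at exact requested gap
distances, and miRNA precursors embedded verbatim in designated lncRNAs.

Everything is a pure function of :class:`SimulationConfig`; the same seed
yields byte-identical files.  Ground truth is recorded in
:class:`SimTruth` and is verifiable against the emitted files by
independent re-parsing.

Construction guarantees used by downstream recovery tests:

* planted lncRNA transcript sequences contain no ``ATG``, so their longest
  ORF is zero and the coding-potential composite can never call them coding;
* coding contaminants carry a planted long ORF built from A/C-only codons,
  so no stop codon or spurious ``ATG`` can arise anywhere in the ORF body;
* the two host bases flanking an embedded precursor are set to ``CC`` so no
  ``ATG`` can span the junction while the embedded copy stays verbatim.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import io as lio
from .expression import CountMatrix
from .models import GeneModel, GenomeAnnotation, TranscriptModel

_BASES = np.array(list("ACGT"))
# codons over {A, C}: never a stop, never part of an ATG
_SAFE_CODONS = ["AAA", "AAC", "ACA", "ACC", "CAA", "CAC", "CCA", "CCC"]

# rng stream ids, fanned out from the single config seed
_STREAM_GENOME, _STREAM_COUNTS, _STREAM_TERMS = 0, 1, 2


class PlacementError(ValueError):
    """Raised when the configured loci do not fit on the configured genome."""


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults are the bundled study conditions."""

    seed: int = 0
    n_chromosomes: int = 3
    chrom_length: int = 600_000
    n_coding_genes: int = 300
    n_lncrna_per_class: int = 6
    n_short_fragments: int = 6
    n_coding_contaminants: int = 6
    group_sizes: tuple[int, int] = (3, 3)
    library_sizes: Optional[tuple[float, ...]] = None
    nb_dispersion: float = 0.02
    de_fraction: float = 0.05
    de_log2fc: float = 3.0
    cis_distance_spec: tuple[int, ...] = (5_000, 20_000, 50_000, 99_999)
    cis_pair_trends: Optional[tuple[tuple[str, str], ...]] = None
    precursor_embed_count: int = 9
    precursor_length: int = 80
    # expression scale: lognormal base means; mRNAs ~10x lncRNAs, and
    # force-planted features (cis pairs, precursor hosts) anchored high so
    # their differential expression is reliably detectable at n=3
    mrna_mean: float = 300.0
    lncrna_mean: float = 30.0
    mean_sigma: float = 0.6
    planted_feature_mean: float = 500.0
    n_terms: int = 10
    term_size: int = 15

    def validate(self) -> None:
        counts = dict(
            n_chromosomes=self.n_chromosomes, chrom_length=self.chrom_length,
            n_coding_genes=self.n_coding_genes,
            n_lncrna_per_class=self.n_lncrna_per_class,
            n_short_fragments=self.n_short_fragments,
            n_coding_contaminants=self.n_coding_contaminants,
            precursor_embed_count=self.precursor_embed_count,
            precursor_length=self.precursor_length,
        )
        for k, v in counts.items():
            if v < 0:
                raise ValueError(f"{k} must be >= 0, got {v}")
        if self.n_chromosomes < 1 or self.chrom_length < 10_000:
            raise ValueError("need >=1 chromosome of >=10 kb")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.de_log2fc <= 0:
            raise ValueError("de_log2fc must be > 0")
        if any(g < 1 for g in self.group_sizes):
            raise ValueError("group sizes must be >= 1")
        if self.n_coding_genes < 3 * self.n_lncrna_per_class:
            raise ValueError(
                "need n_coding_genes >= 3 * n_lncrna_per_class to host the "
                "intronic/antisense/exonic classes"
            )
        n_lnc = 4 * self.n_lncrna_per_class + len(self.cis_distance_spec)
        if self.precursor_embed_count > n_lnc:
            raise ValueError("more precursor embeddings requested than lncRNAs")
        if self.precursor_embed_count and self.precursor_length + 110 > 600:
            raise ValueError("precursor_length too long for the 600-nt hosts")
        if self.trends_resolved() and len(self.trends_resolved()) != len(
            self.cis_distance_spec
        ):
            raise ValueError("cis_pair_trends must align with cis_distance_spec")

    def trends_resolved(self) -> tuple[tuple[str, str], ...]:
        """DE direction pair per planted cis pair; default alternates
        concordant up/up and down/down with one discordant pair at the end
        when four or more pairs are requested."""
        if self.cis_pair_trends is not None:
            return self.cis_pair_trends
        n = len(self.cis_distance_spec)
        trends = [("up", "up") if i % 2 == 0 else ("down", "down") for i in range(n)]
        if n >= 4:
            trends[-1] = ("up", "down")
        return tuple(trends)

    def n_samples(self) -> int:
        return sum(self.group_sizes)


@dataclass
class SimTruth:
    """Ground truth planted by the generator, keyed by emitted ids."""

    de_features: dict[str, tuple[str, float]] = field(default_factory=dict)
    class_labels: dict[str, str] = field(default_factory=dict)
    cis_pairs_planted: list[tuple[str, str, int]] = field(default_factory=list)
    cis_pair_trends: list[tuple[str, str]] = field(default_factory=list)
    precursor_embeddings: list[tuple[str, str, tuple[int, int]]] = field(
        default_factory=list
    )
    precursor_seqs: dict[str, str] = field(default_factory=dict)
    candidates: list[TranscriptModel] = field(default_factory=list)
    candidate_category: dict[str, str] = field(default_factory=dict)
    enriched_term: Optional[str] = None

    def lncrna_ids(self) -> list[str]:
        return [t.transcript_id for t in self.candidates
                if self.candidate_category[t.transcript_id] == "lncrna"]


# ---------------------------------------------------------------------------
# sequence helpers


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _strip_atg(seq: str) -> str:
    """Remove every ATG by mutating its G to C (cannot create a new ATG)."""
    s = list(seq)
    for i in range(len(s) - 2):
        if s[i] == "A" and s[i + 1] == "T" and s[i + 2] == "G":
            s[i + 2] = "C"
    return "".join(s)


def _atg_free_seq(rng: np.random.Generator, n: int) -> str:
    return _strip_atg(_random_seq(rng, n))


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _contaminant_seq(rng: np.random.Generator, length: int, orf_nt: int = 630) -> str:
    """ATG-free background with one planted ORF of ``orf_nt`` nt at offset 100."""
    if length < 100 + orf_nt + 50:
        raise ValueError("contaminant transcript too short for planted ORF")
    body = "".join(
        _SAFE_CODONS[i] for i in rng.integers(0, len(_SAFE_CODONS), orf_nt // 3 - 2)
    )
    orf = "ATG" + body + "TAA"
    bg = _atg_free_seq(rng, length)
    # CC pads block ATG formation across the ORF junctions
    return bg[:98] + "CC" + orf + "CC" + bg[100 + orf_nt + 2:]


def _embed(host: str, insert: str, offset0: int) -> str:
    """Place ``insert`` verbatim at 0-based ``offset0``, with CC pads on both
    sides so no ATG can span a junction."""
    end = offset0 + len(insert)
    return host[: offset0 - 2] + "CC" + insert + "CC" + host[end + 2:]


# ---------------------------------------------------------------------------
# locus geometry (offsets relative to a block start)

_EXON_LEN, _INTRON_LEN = 300, 500
_GENE_SPAN = 3 * _EXON_LEN + 2 * _INTRON_LEN  # 1900
_BUFFER = 1000  # minimum spacing between placed blocks


def _gene_exons(start: int) -> tuple[tuple[int, int], ...]:
    e = []
    pos = start
    for _ in range(3):
        e.append((pos, pos + _EXON_LEN - 1))
        pos += _EXON_LEN + _INTRON_LEN
    return tuple(e)


class _Placer:
    """Sequential block placement with buffers across chromosomes."""

    def __init__(self, n_chrom: int, chrom_length: int) -> None:
        self.chroms = [f"chr{i + 1}" for i in range(n_chrom)]
        self.length = chrom_length
        self.cursor = {c: _BUFFER + 1 for c in self.chroms}
        self.idx = 0

    def place(self, width: int) -> tuple[str, int]:
        while self.idx < len(self.chroms):
            chrom = self.chroms[self.idx]
            start = self.cursor[chrom]
            if start + width + _BUFFER <= self.length:
                self.cursor[chrom] = start + width + _BUFFER
                return chrom, start
            self.idx += 1
        raise PlacementError(
            f"cannot place a {width}-bp block: increase chrom_length or "
            f"n_chromosomes"
        )


# ---------------------------------------------------------------------------
# genome + assembly design


def simulate_genome(
    config: SimulationConfig,
) -> tuple[GenomeAnnotation, dict[str, str], SimTruth]:
    """Design the reference annotation, genome sequence and all planted truth.

    The full candidate design (assembly transcripts, their sequences, DE
    plan) is decided here and recorded in the returned :class:`SimTruth`;
    :func:`simulate_assembly` and :func:`simulate_counts` realise it.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_GENOME])
    placer = _Placer(config.n_chromosomes, config.chrom_length)
    truth = SimTruth()

    genes: list[GeneModel] = []
    # designed transcript sequences written into the genome after background fill
    designed: list[tuple[TranscriptModel, str]] = []

    def add_gene(gid: str, chrom: str, start: int, strand: str) -> GeneModel:
        exons = _gene_exons(start)
        t = TranscriptModel(f"{gid}.t1", chrom, strand, exons, gid)
        g = GeneModel(gid, chrom, strand, exons[0][0], exons[-1][1], "coding", [t])
        genes.append(g)
        return g

    # plain coding genes (hosts for intronic/antisense/exonic lncRNAs)
    for i in range(config.n_coding_genes):
        chrom, start = placer.place(_GENE_SPAN)
        add_gene(f"G{i + 1:04d}", chrom, start, "+" if i % 2 == 0 else "-")
    plain_genes = list(genes)

    # cis-pair blocks: gene + downstream intergenic lncRNA at an exact gap
    cis_lnc: list[TranscriptModel] = []
    for j, gap in enumerate(config.cis_distance_spec):
        lnc_len = 600
        width = _GENE_SPAN + gap + 1 + lnc_len
        chrom, start = placer.place(width)
        g = add_gene(f"CG{j + 1:03d}", chrom, start, "+")
        lnc_start = g.end + gap + 1
        t = TranscriptModel(
            f"LNC_CIS{j + 1:03d}", chrom, "+", ((lnc_start, lnc_start + lnc_len - 1),)
        )
        cis_lnc.append(t)
        truth.class_labels[t.transcript_id] = "intergenic"
        truth.cis_pairs_planted.append((t.transcript_id, g.gene_id, gap))
        designed.append((t, _atg_free_seq(rng, lnc_len)))
    truth.cis_pair_trends = list(config.trends_resolved())

    # positional-class lncRNAs hosted by distinct plain genes
    hosted: list[TranscriptModel] = []
    n_cls = config.n_lncrna_per_class
    for k in range(n_cls):
        host = plain_genes[k]
        intron = host.transcripts[0].introns[0]
        s = intron[0] + 40
        t = TranscriptModel(f"LNC_INT{k + 1:03d}", host.chrom, host.strand,
                            ((s, s + 399),))
        truth.class_labels[t.transcript_id] = "intronic"
        hosted.append(t)
    for k in range(n_cls):
        host = plain_genes[n_cls + k]
        exon2 = host.transcripts[0].exons[1]
        s = exon2[0] + 200  # overlaps exon2 by 100 bp, runs into intron 2
        strand = "-" if host.strand == "+" else "+"
        t = TranscriptModel(f"LNC_AS{k + 1:03d}", host.chrom, strand, ((s, s + 499),))
        truth.class_labels[t.transcript_id] = "antisense"
        hosted.append(t)
    for k in range(n_cls):
        host = plain_genes[2 * n_cls + k]
        exon2 = host.transcripts[0].exons[1]
        s = exon2[0] + 200
        t = TranscriptModel(f"LNC_EX{k + 1:03d}", host.chrom, host.strand,
                            ((s, s + 499),))
        truth.class_labels[t.transcript_id] = "exonic_sense_overlap"
        hosted.append(t)
    for t in hosted:
        designed.append((t, _atg_free_seq(rng, t.length)))

    # free-standing intergenic lncRNAs (alternating 1- and 2-exon structure)
    intergenic: list[TranscriptModel] = []
    for k in range(n_cls):
        if k % 2 == 0:
            width, exonf = 600, lambda s: ((s, s + 599),)
        else:
            width, exonf = 900, lambda s: ((s, s + 299), (s + 600, s + 899))
        chrom, start = placer.place(width)
        t = TranscriptModel(f"LNC_IG{k + 1:03d}", chrom,
                            "+" if k % 2 == 0 else "-", exonf(start))
        truth.class_labels[t.transcript_id] = "intergenic"
        intergenic.append(t)
        designed.append((t, _atg_free_seq(rng, t.length)))

    # short fragments and coding contaminants at their own loci
    fragments, contaminants = [], []
    for k in range(config.n_short_fragments):
        chrom, start = placer.place(150)
        t = TranscriptModel(f"FRAG{k + 1:03d}", chrom, "+", ((start, start + 149),))
        fragments.append(t)
        designed.append((t, _atg_free_seq(rng, 150)))
    for k in range(config.n_coding_contaminants):
        chrom, start = placer.place(900)
        t = TranscriptModel(f"CONT{k + 1:03d}", chrom, "+", ((start, start + 899),))
        contaminants.append(t)
        designed.append((t, _contaminant_seq(rng, 900)))

    # precursor embeddings into the first hosts in deterministic order
    lnc_order = cis_lnc + intergenic + hosted
    seq_by_id = {t.transcript_id: s for t, s in designed}
    for k in range(config.precursor_embed_count):
        host_t = lnc_order[k]
        pid = f"PRE{k + 1:03d}"
        pseq = _atg_free_seq(rng, config.precursor_length)
        offset0 = 100
        seq_by_id[host_t.transcript_id] = _embed(
            seq_by_id[host_t.transcript_id], pseq, offset0
        )
        truth.precursor_seqs[pid] = pseq
        truth.precursor_embeddings.append(
            (host_t.transcript_id, pid, (offset0 + 1, offset0 + config.precursor_length))
        )
    designed = [(t, seq_by_id[t.transcript_id]) for t, _ in designed]

    # genome: random background, then the designed transcripts written in
    genome_arr = {
        c: rng.integers(0, 4, size=config.chrom_length).astype(np.uint8)
        for c in placer.chroms
    }
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    for t, seq in designed:
        region = seq if t.strand == "+" else _revcomp(seq)
        pos = 0
        arr = genome_arr[t.chrom]
        for s, e in t.exons:
            n = e - s + 1
            chunk = np.frombuffer(region[pos:pos + n].encode(), dtype=np.uint8)
            # map ACGT letters back to 0..3 codes
            codes = np.searchsorted(lut, chunk)
            arr[s - 1:e] = codes
            pos += n
    genome = {c: "".join(_BASES[a]) for c, a in genome_arr.items()}

    # assembly candidate set: rediscoveries + fragments + contaminants + lncRNAs
    candidates: list[TranscriptModel] = []
    for g in genes:
        ref = g.transcripts[0]
        c = TranscriptModel(f"ASM_{ref.transcript_id}", ref.chrom, ref.strand,
                            ref.exons)
        candidates.append(c)
        truth.candidate_category[c.transcript_id] = "known_mrna"
    for t in fragments:
        candidates.append(t)
        truth.candidate_category[t.transcript_id] = "short_fragment"
    for t in contaminants:
        candidates.append(t)
        truth.candidate_category[t.transcript_id] = "coding_contaminant"
    for t in lnc_order:
        candidates.append(t)
        truth.candidate_category[t.transcript_id] = "lncrna"
    truth.candidates = candidates

    _plan_de(config, truth, [g.gene_id for g in genes], rng)

    annotation = GenomeAnnotation(genes)
    return annotation, genome, truth


def _plan_de(
    config: SimulationConfig,
    truth: SimTruth,
    gene_ids: list[str],
    rng: np.random.Generator,
) -> None:
    """Record planted differential expression: forced for cis pairs and
    precursor hosts, then a random ``de_fraction`` of the rest."""
    lfc = config.de_log2fc
    for (lnc_id, gene_id, _), (d_lnc, d_gene) in zip(
        truth.cis_pairs_planted, truth.cis_pair_trends
    ):
        truth.de_features[lnc_id] = (d_lnc, lfc)
        truth.de_features[gene_id] = (d_gene, lfc)
    for k, (host_id, _, _) in enumerate(truth.precursor_embeddings):
        if host_id not in truth.de_features:
            truth.de_features[host_id] = ("up" if k % 2 == 0 else "down", lfc)
    pool = sorted(
        (set(gene_ids) | set(truth.lncrna_ids())) - set(truth.de_features)
    )
    n_extra = int(round(config.de_fraction * len(pool)))
    chosen = rng.choice(len(pool), size=min(n_extra, len(pool)), replace=False)
    for i in sorted(chosen):
        truth.de_features[pool[i]] = ("up" if rng.random() < 0.5 else "down", lfc)


def simulate_assembly(
    annotation: GenomeAnnotation,
    genome: dict[str, str],
    truth: SimTruth,
    config: SimulationConfig,
) -> tuple[list[TranscriptModel], dict[str, str]]:
    """Materialise the candidate transcript set and its spliced sequences."""
    seqs: dict[str, str] = {}
    from Bio.Seq import Seq

    for t in truth.candidates:
        parts = [genome[t.chrom][s - 1:e] for s, e in t.exons]
        seq = "".join(parts)
        if t.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        seqs[t.transcript_id] = seq
    return list(truth.candidates), seqs


# ---------------------------------------------------------------------------
# counts


def feature_table(
    annotation: GenomeAnnotation, truth: SimTruth
) -> pd.DataFrame:
    """Quantifiable features: genes (as mRNAs) plus every non-rediscovery
    candidate, with lengths and kinds."""
    rows = []
    for g in annotation:
        rows.append((g.gene_id, "mRNA", g.transcripts[0].length))
    for t in truth.candidates:
        cat = truth.candidate_category[t.transcript_id]
        if cat == "known_mrna":
            continue
        kind = "lncRNA" if cat == "lncrna" else "other"
        rows.append((t.transcript_id, kind, t.length))
    return pd.DataFrame(rows, columns=["feature_id", "kind", "length"])


def simulate_counts(
    features: pd.DataFrame,
    truth: Optional[SimTruth],
    config: SimulationConfig,
) -> CountMatrix:
    """Draw NB(mean, dispersion) counts with planted fold changes.

    ``features`` needs columns ``feature_id``, ``length`` and optionally
    ``kind`` and ``base_mean``.  Variance is mean + dispersion * mean^2.
    Planted DE features have the group-2 mean scaled by 2**(+/-log2fc).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_COUNTS])
    features = features.reset_index(drop=True)
    n = len(features)
    kinds = features["kind"] if "kind" in features else pd.Series(["lncRNA"] * n)

    if "base_mean" in features:
        base = features["base_mean"].to_numpy(float)
    else:
        mu = np.where(kinds.to_numpy() == "mRNA",
                      np.log(config.mrna_mean), np.log(config.lncrna_mean))
        base = np.exp(rng.normal(mu, config.mean_sigma))

    de = truth.de_features if truth is not None else {}
    forced = set()
    if truth is not None:
        forced = {i for p in truth.cis_pairs_planted for i in p[:2]}
        forced |= {h for h, _, _ in truth.precursor_embeddings}
    fids = features["feature_id"].to_numpy()
    for i, fid in enumerate(fids):
        if fid in forced:
            base[i] = max(base[i], config.planted_feature_mean)

    n1, n2 = config.group_sizes
    sample_ids = [f"g1_s{i + 1}" for i in range(n1)] + [
        f"g2_s{i + 1}" for i in range(n2)
    ]
    groups = {s: ("group1" if s.startswith("g1") else "group2") for s in sample_ids}
    libs = (np.ones(n1 + n2) if config.library_sizes is None
            else np.asarray(config.library_sizes, float))
    if len(libs) != n1 + n2:
        raise ValueError("library_sizes length must equal total sample count")
    libs = libs / libs.mean()

    mean1 = base.copy()
    mean2 = base.copy()
    for i, fid in enumerate(fids):
        if fid in de:
            direction, lfc = de[fid]
            mean2[i] = base[i] * 2.0 ** (lfc if direction == "up" else -lfc)

    means = np.column_stack([mean1] * n1 + [mean2] * n2) * libs[None, :]
    alpha = config.nb_dispersion
    r = 1.0 / alpha
    p = r / (r + means)
    counts = rng.negative_binomial(r, p)
    df = pd.DataFrame(counts, index=fids, columns=sample_ids)
    return CountMatrix(
        counts=df,
        groups=groups,
        lengths=pd.Series(features["length"].to_numpy(), index=fids),
        kinds=pd.Series(kinds.to_numpy(), index=fids),
    )


# ---------------------------------------------------------------------------
# gene sets


def simulate_gene_sets(
    annotation: GenomeAnnotation,
    truth: SimTruth,
    config: SimulationConfig,
) -> dict[str, tuple[str, list[str]]]:
    """Random GMT-style terms over the gene universe plus one term deliberately
    enriched for planted DE genes."""
    rng = np.random.default_rng([config.seed, _STREAM_TERMS])
    gene_ids = sorted(g.gene_id for g in annotation)
    de_genes = sorted(set(gene_ids) & set(truth.de_features))
    non_de = sorted(set(gene_ids) - set(de_genes))

    terms: dict[str, tuple[str, list[str]]] = {}
    for i in range(config.n_terms):
        size = min(config.term_size, len(gene_ids))
        pick = rng.choice(len(gene_ids), size=size, replace=False)
        terms[f"TERM{i + 1:03d}"] = (
            f"random pathway {i + 1}",
            sorted(gene_ids[j] for j in pick),
        )
    n_hit = min(len(de_genes), max(1, int(0.8 * config.term_size)))
    n_miss = min(len(non_de), config.term_size - n_hit)
    hit = [de_genes[j] for j in rng.choice(len(de_genes), n_hit, replace=False)] \
        if de_genes else []
    miss = [non_de[j] for j in rng.choice(len(non_de), n_miss, replace=False)] \
        if non_de else []
    tid = f"TERM{config.n_terms + 1:03d}"
    terms[tid] = ("planted enriched pathway", sorted(hit + miss))
    truth.enriched_term = tid
    return terms


# ---------------------------------------------------------------------------
# dataset writer


def write_dataset(config: SimulationConfig, outdir: str | os.PathLike) -> dict[str, str]:
    """Generate everything and write the plain-text dataset; returns a
    name -> path manifest."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    annotation, genome, truth = simulate_genome(config)
    candidates, cand_seqs = simulate_assembly(annotation, genome, truth, config)
    feats = feature_table(annotation, truth)
    cm = simulate_counts(feats, truth, config)
    terms = simulate_gene_sets(annotation, truth, config)

    paths = {k: os.path.join(outdir, v) for k, v in {
        "reference_gtf": "reference.gtf",
        "genome_fasta": "genome.fa",
        "assembly_gtf": "assembly.gtf",
        "assembly_fasta": "assembly.fa",
        "counts_tsv": "counts.tsv",
        "groups_tsv": "groups.tsv",
        "features_tsv": "features.tsv",
        "precursor_fasta": "precursors.fa",
        "gene_sets_gmt": "gene_sets.gmt",
        "truth_de_tsv": "truth_de.tsv",
        "truth_classes_tsv": "truth_classes.tsv",
        "truth_cis_tsv": "truth_cis.tsv",
        "truth_precursors_tsv": "truth_precursors.tsv",
    }.items()}

    lio.write_gtf_annotation(annotation, paths["reference_gtf"])
    lio.write_fasta(genome, paths["genome_fasta"])
    lio.write_gtf_transcripts(candidates, paths["assembly_gtf"])
    lio.write_fasta(cand_seqs, paths["assembly_fasta"])
    lio.write_counts(cm.counts, cm.groups, paths["counts_tsv"], paths["groups_tsv"])
    lio.write_tsv(feats, paths["features_tsv"])
    lio.write_fasta(truth.precursor_seqs, paths["precursor_fasta"])
    lio.write_gmt(terms, paths["gene_sets_gmt"])

    lio.write_tsv(
        pd.DataFrame(
            [(f, d, l) for f, (d, l) in sorted(truth.de_features.items())],
            columns=["feature_id", "direction", "log2fc"],
        ),
        paths["truth_de_tsv"],
    )
    lio.write_tsv(
        pd.DataFrame(
            sorted(truth.class_labels.items()),
            columns=["transcript_id", "class"],
        ),
        paths["truth_classes_tsv"],
    )
    lio.write_tsv(
        pd.DataFrame(
            [(l, g, gap, t[0], t[1]) for (l, g, gap), t in
             zip(truth.cis_pairs_planted, truth.cis_pair_trends)],
            columns=["lncrna_id", "gene_id", "gap_bp", "lnc_trend", "gene_trend"],
        ),
        paths["truth_cis_tsv"],
    )
    lio.write_tsv(
        pd.DataFrame(
            [(h, p, s, e) for h, p, (s, e) in truth.precursor_embeddings],
            columns=["lncrna_id", "precursor_id", "start", "end"],
        ),
        paths["truth_precursors_tsv"],
    )
    return paths
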