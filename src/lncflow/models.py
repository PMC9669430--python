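"""Core genomic domain objects shared across the pipeline.

Coordinates are 1-based closed intervals throughout (GTF convention); a
single-base feature has start == end and length 1.  Exon lists are kept
sorted and disjoint so that intron chains and spliced lengths are
well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

#: Positional classes assigned to retained lncRNAs, in precedence order.
LNCRNA_CLASSES = ("exonic_sense_overlap", "antisense", "intronic", "intergenic")


@dataclass(frozen=True)
class TranscriptModel:
    """An exon-structured transcript on one chromosome and strand."""

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        prev_end = 0
        for start, end in self.exons:
            if start < 1 or end < start:
                raise ValueError(
                    f"{self.transcript_id}: bad exon interval ({start}, {end})"
                )
            if start <= prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons must be sorted and disjoint"
                )
            prev_end = end

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        """Spliced length in bp (sum of exon lengths)."""
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Intron intervals between consecutive exons (may be empty)."""
        return tuple(
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        )

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return self.introns

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


@dataclass
class GeneModel:
    """A gene locus grouping one or more transcripts."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str  # "coding" | "noncoding"
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


@dataclass
class GenomeAnnotation:
    """A set of gene models indexed by id, the reference for classification."""

    genes: list[GeneModel]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("gene_ids must be unique")
        self._by_id = {g.gene_id: g for g in self.genes}

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def get(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def coding_genes(self) -> list[GeneModel]:
        return [g for g in self.genes if g.biotype == "coding"]

    def coding_transcripts(self) -> list[TranscriptModel]:
        return [t for g in self.coding_genes() for t in g.transcripts]

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return [g for g in self.genes if g.chrom == chrom]


@dataclass(frozen=True)
class CodingPotentialScore:
    """ORF and Fickett-statistic features plus the composite call."""

    longest_orf_nt: int
    orf_coverage: float
    fickett: float
    label: str  # "coding" | "noncoding"

    def __post_init__(self) -> None:
        if not 0.0 <= self.orf_coverage <= 1.0:
            raise ValueError("orf_coverage must lie in [0, 1]")
        if self.label not in ("coding", "noncoding"):
            raise ValueError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class CisPair:
    """A lncRNA-gene proximity relation within the cis window."""

    lncrna_id: str
    gene_id: str
    gap_bp: int  # 0 when the spans overlap
    relation: str  # "overlap" | "upstream" | "downstream" (relative to gene strand)

    def __post_init__(self) -> None:
        if self.gap_bp < 0:
            raise ValueError("gap_bp must be >= 0")
        if self.relation not in ("overlap", "upstream", "downstream"):
            raise ValueError(f"unknown relation {self.relation!r}")


@dataclass(frozen=True)
class AlignmentHit:
    """Best local alignment of a lncRNA query against a precursor subject."""

    query_id: str
    subject_id: str
    score: float
    identity: float
    coverage: float  # fraction of the subject covered by the alignment

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("local alignment score must be >= 0")
        for name in ("identity", "coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class NetworkEdge:
    """A DEL-DEM edge carrying both differential-expression directions."""

    del_id: str
    dem_id: str
    del_direction: str
    dem_direction: str

    @property
    def concordant(self) -> bool:
        return self.del_direction == self.dem_direction


def interval_gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Number of bases strictly between two closed intervals (0 if they touch
    or overlap)."""
    if a[0] > b[1]:
        return a[0] - b[1] - 1
    if b[0] > a[1]:
        return b[0] - a[1] - 1
    return 0


def make_transcripts(
    records: Sequence[tuple[str, str, str, Sequence[tuple[int, int]], Optional[str]]],
) -> list[TranscriptModel]:
    """Convenience constructor from (id, chrom, strand, exons, gene_id) tuples."""
    return [
        TranscriptModel(tid, chrom, strand, tuple(tuple(e) for e in exons), gene_id)
        for tid, chrom, strand, exons, gene_id in records
    ]
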