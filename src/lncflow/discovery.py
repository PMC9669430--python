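"""lncRNA identification: candidate filtering, coding potential, positional class.

The discovery stage mirrors the standard lncRNA-seq workflow: drop
re-assembled known mRNAs and sub-200-nt fragments, score the survivors'
protein-coding potential, and classify the noncoding remainder by where
they sit relative to the coding annotation (exonic sense overlap,
antisense, intronic, intergenic).

Coding potential is a transparent composite of two classic sequence
features — the longest ATG..stop open reading frame and the Fickett
TESTCODE statistic — standing in for trained classifiers such as CPC/CNCI.
A transcript is called coding when it has a long ORF outright, or a
coding-like Fickett value combined with substantial ORF coverage.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import pandas as pd

from .models import (
    CodingPotentialScore,
    GenomeAnnotation,
    LNCRNA_CLASSES,
    TranscriptModel,
)

_STOPS = {"TAA", "TAG", "TGA"}
_ALPHABET = set("ACGT")


def _check_alphabet(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)}")
    return seq


# ---------------------------------------------------------------------------
# candidate filtering


def _structure_key(t: TranscriptModel) -> tuple:
    """Exact-match key: intron chain for multi-exon transcripts, the exon
    interval itself for single-exon ones."""
    if t.n_exons == 1:
        return (t.chrom, t.strand, "exon", t.exons)
    return (t.chrom, t.strand, "introns", t.intron_chain)


def filter_candidates(
    candidates: Sequence[TranscriptModel],
    reference: GenomeAnnotation,
    min_len: int = 200,
) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Remove known mRNAs and short transcripts from the candidate set.

    A candidate is removed iff its structure exactly matches a reference
    coding transcript (same chromosome, strand and intron boundaries; exact
    interval equality for single-exon models), or its spliced length is
    strictly below ``min_len``.  Survivor order is preserved.

    Returns the retained list and a per-candidate table with columns
    ``transcript_id``, ``retained``, ``reason`` (``known_mrna``/``short``
    for removals, empty otherwise) and ``flag`` (``unknown_chrom`` when the
    candidate's chromosome is absent from the reference).
    """
    known = {_structure_key(t) for t in reference.coding_transcripts()}
    ref_chroms = {g.chrom for g in reference}

    retained: list[TranscriptModel] = []
    rows = []
    for t in candidates:
        flag = ""
        if t.chrom not in ref_chroms:
            warnings.warn(
                f"{t.transcript_id}: chromosome {t.chrom!r} not in reference",
                stacklevel=2,
            )
            flag = "unknown_chrom"
        if _structure_key(t) in known:
            rows.append((t.transcript_id, False, "known_mrna", flag))
        elif t.length < min_len:
            rows.append((t.transcript_id, False, "short", flag))
        else:
            retained.append(t)
            rows.append((t.transcript_id, True, "", flag))
    table = pd.DataFrame(rows, columns=["transcript_id", "retained", "reason", "flag"])
    return retained, table


# ---------------------------------------------------------------------------
# ORF


def longest_orf(seq: str) -> tuple[int, int, Optional[int]]:
    """Longest ATG..stop open reading frame on the given (sense) strand.

    Returns ``(start, length_nt, frame)`` with a 1-based start and the stop
    codon included in the length; ``(0, 0, None)`` when no complete ORF
    exists.  Ties are broken towards the smallest start position.
    """
    seq = _check_alphabet(seq)
    n = len(seq)
    best = (0, 0, None)
    for frame in range(3):
        start0: Optional[int] = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if start0 is None:
                if codon == "ATG":
                    start0 = i
            elif codon in _STOPS:
                length = i + 3 - start0
                if length > best[1] or (length == best[1] and best[1] > 0
                                        and start0 + 1 < best[0]):
                    best = (start0 + 1, length, frame)
                start0 = None
    return best


# ---------------------------------------------------------------------------
# Fickett TESTCODE

# Published TESTCODE lookup tables: for each base, the probability of coding
# given the binned position parameter (max/min positional asymmetry) or
# binned composition, with the published weights.
_POSITION_PARA = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0)
_CONTENT_PARA = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0)
_POSITION_PROB = {
    "A": (0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22),
    "C": (0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23),
    "G": (0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08),
    "T": (0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09),
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_CONTENT_PROB = {
    "A": (0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21),
    "C": (0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31),
    "G": (0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29),
    "T": (0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58),
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}


def _lookup(value: float, para: tuple, prob: tuple) -> float:
    for threshold, p in zip(para, prob):
        if value >= threshold:
            return p
    return prob[-1]


def fickett_score(seq: str) -> float:
    """Fickett TESTCODE statistic combining positional asymmetry and
    composition of each base; higher values are more coding-like
    (>= 0.95 coding, <= 0.74 noncoding in the original reading frame test).
    """
    seq = _check_alphabet(seq)
    if len(seq) < 3:
        raise ValueError("need at least 3 bases for the TESTCODE statistic")
    score = 0.0
    n = len(seq)
    for base in "ACGT":
        counts = [seq[k::3].count(base) for k in range(3)]
        position = max(counts) / (min(counts) + 1.0)
        content = sum(counts) / n
        score += _POSITION_WEIGHT[base] * _lookup(
            position, _POSITION_PARA, _POSITION_PROB[base]
        )
        score += _CONTENT_WEIGHT[base] * _lookup(
            content, _CONTENT_PARA, _CONTENT_PROB[base]
        )
    return score


# ---------------------------------------------------------------------------
# composite coding-potential call


def coding_potential(
    seq: str,
    orf_min: int = 300,
    fickett_cut: float = 0.95,
    cov_min: float = 0.5,
) -> CodingPotentialScore:
    """Composite coding/noncoding call from ORF length and Fickett statistic.

    ``coding`` iff the longest ORF is >= ``orf_min`` nt, or the Fickett
    value is >= ``fickett_cut`` while the ORF covers >= ``cov_min`` of the
    transcript.
    """
    seq = _check_alphabet(seq)
    if not seq:
        raise ValueError("empty sequence")
    _, orf_nt, _ = longest_orf(seq)
    coverage = orf_nt / len(seq)
    fickett = fickett_score(seq) if len(seq) >= 3 else 0.26
    is_coding = (orf_nt >= orf_min) or (fickett >= fickett_cut and coverage >= cov_min)
    return CodingPotentialScore(
        longest_orf_nt=orf_nt,
        orf_coverage=coverage,
        fickett=fickett,
        label="coding" if is_coding else "noncoding",
    )


# ---------------------------------------------------------------------------
# positional classification


def classify_lncrna(t: TranscriptModel, reference: GenomeAnnotation) -> str:
    """Assign exactly one positional class, in fixed precedence order:
    exonic sense overlap > antisense > intronic > intergenic."""
    coding_ts = [
        tr for tr in reference.coding_transcripts() if tr.chrom == t.chrom
    ]

    def exon_overlap(tr: TranscriptModel) -> bool:
        return any(
            es <= qe and qs <= ee
            for qs, qe in t.exons
            for es, ee in tr.exons
        )

    if any(tr.strand == t.strand and exon_overlap(tr) for tr in coding_ts):
        return "exonic_sense_overlap"
    if any(tr.strand != t.strand and exon_overlap(tr) for tr in coding_ts):
        return "antisense"
    for tr in coding_ts:
        for is_, ie in tr.introns:
            if is_ <= t.start and t.end <= ie:
                return "intronic"
    return "intergenic"


def classify_all(
    transcripts: Sequence[TranscriptModel], reference: GenomeAnnotation
) -> pd.DataFrame:
    """Classify every transcript; returns a table with id, class, exon count
    and spliced length."""
    rows = [
        (t.transcript_id, classify_lncrna(t, reference), t.n_exons, t.length)
        for t in transcripts
    ]
    return pd.DataFrame(rows, columns=["transcript_id", "class", "n_exons", "length"])


def class_summary(classified: pd.DataFrame) -> pd.DataFrame:
    """Aggregate class counts (the positional-distribution table)."""
    counts = classified["class"].value_counts()
    return pd.DataFrame(
        {"class": LNCRNA_CLASSES,
         "count": [int(counts.get(c, 0)) for c in LNCRNA_CLASSES]}
    )


def structure_histograms(classified: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Exon-count and length histograms of retained lncRNAs."""
    exon_hist = (
        classified["n_exons"].value_counts().sort_index().rename_axis("n_exons")
        .reset_index(name="count")
    )
    length_bins = pd.cut(classified["length"], bins=[0, 200, 400, 600, 800, 1000,
                                                     2000, 5000, float("inf")])
    length_hist = (
        length_bins.value_counts().sort_index().rename_axis("length_bin")
        .reset_index(name="count")
    )
    length_hist["length_bin"] = length_hist["length_bin"].astype(str)
    return {"exon_counts": exon_hist, "lengths": length_hist}
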