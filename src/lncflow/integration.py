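"""lncRNA-mRNA integration: cis targets, precursor homology, core networks.

Three analyses link differentially expressed lncRNAs (DELs) to mRNAs:

* **cis-target prediction** — a protein-coding gene is a candidate cis
  target of a lncRNA when their genomic spans overlap or lie within a
  fixed window (default strictly < 100 kb) on the same chromosome,
  strand-agnostic;
* **miRNA-precursor homology** — Smith-Waterman local alignment of each
  DEL against a precursor database, a DEL counting as precursor-bearing
  when some precursor aligns at high identity over most of its length;
* **core network construction** — DEL-DEM edges wherever a DEM's gene is
  a cis target of the DEL, split into concordant (same differential
  direction) and discordant edges.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .models import (
    AlignmentHit,
    CisPair,
    GenomeAnnotation,
    NetworkEdge,
    TranscriptModel,
    interval_gap,
)

_ALPHABET = set("ACGT")


# ---------------------------------------------------------------------------
# cis-target prediction


def predict_cis_targets(
    dels: Sequence[TranscriptModel],
    reference: GenomeAnnotation,
    window: int = 100_000,
) -> list[CisPair]:
    """Coding genes overlapping or within ``window`` bp of each lncRNA.

    The gap is the number of bases strictly between the two closed spans
    (0 on overlap); a pair is emitted iff the spans overlap or gap <
    ``window`` (strict).  Each (lncRNA, gene) pair appears once.
    """
    genes_by_chrom: dict[str, list] = {}
    for g in reference.coding_genes():
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    for gs in genes_by_chrom.values():
        gs.sort(key=lambda g: g.start)

    pairs: list[CisPair] = []
    for t in dels:
        for g in genes_by_chrom.get(t.chrom, []):
            if g.start - t.end - 1 >= window:
                break  # genes sorted by start: all later ones are farther
            gap = interval_gap(t.span, g.span)
            overlapping = g.overlaps(t.start, t.end)
            if not overlapping and gap >= window:
                continue
            if overlapping:
                relation = "overlap"
            else:
                genomic_left = t.end < g.start
                relation = (
                    "upstream" if (g.strand == "+") == genomic_left else "downstream"
                )
            pairs.append(CisPair(t.transcript_id, g.gene_id, gap, relation))
    return pairs


def cis_pairs_to_frame(pairs: Iterable[CisPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.lncrna_id, p.gene_id, p.gap_bp, p.relation) for p in pairs],
        columns=["lncrna_id", "gene_id", "gap_bp", "relation"],
    )


# ---------------------------------------------------------------------------
# Smith-Waterman local alignment


def _sw_matrix(
    query: str, subject: str, match: float, mismatch: float, gap: float
) -> np.ndarray:
    """Full Smith-Waterman score matrix with linear gap penalty.

    Rows follow the query, columns the subject.  The left-gap recurrence
    H[i,j] = max(A[j], H[i,j-1] + gap) is closed into a running maximum so
    each row is fully vectorised.
    """
    m, n = len(query), len(subject)
    H = np.zeros((m + 1, n + 1))
    subj = np.frombuffer(subject.encode(), dtype=np.uint8)
    quer = np.frombuffer(query.encode(), dtype=np.uint8)
    offsets = -gap * np.arange(n)
    for i in range(1, m + 1):
        sub = np.where(subj == quer[i - 1], match, mismatch)
        a = np.maximum(0.0, np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + gap))
        H[i, 1:] = np.maximum.accumulate(a + offsets) - offsets
    return H


def local_align(
    query: str,
    subject: str,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentHit:
    """Optimal local alignment by dynamic programming.

    Ties on the optimal score resolve to the lowest end coordinates
    (query first, then subject); the traceback prefers diagonal moves over
    query-gap over subject-gap.  ``identity`` is matches over alignment
    columns; ``coverage`` is the aligned fraction of the subject.
    """
    for s in (query, subject):
        if not s:
            raise ValueError("sequences must be nonempty")
        if set(s.upper()) - _ALPHABET:
            raise ValueError("sequences must be over A/C/G/T")
    query, subject = query.upper(), subject.upper()
    H = _sw_matrix(query, subject, match, mismatch, gap)
    best = float(H.max())
    if best == 0.0:
        return AlignmentHit(query_id, subject_id, 0.0, 0.0, 0.0)
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)

    matches = columns = subj_cols = 0
    while H[i, j] > 0:
        if (
            i > 0 and j > 0
            and H[i, j] == H[i - 1, j - 1]
            + (match if query[i - 1] == subject[j - 1] else mismatch)
        ):
            matches += query[i - 1] == subject[j - 1]
            columns += 1
            subj_cols += 1
            i, j = i - 1, j - 1
        elif i > 0 and H[i, j] == H[i - 1, j] + gap:
            columns += 1
            i -= 1
        else:
            columns += 1
            subj_cols += 1
            j -= 1
    return AlignmentHit(
        query_id,
        subject_id,
        best,
        matches / columns,
        subj_cols / len(subject),
    )


# ---------------------------------------------------------------------------
# precursor scan


def precursor_scan(
    del_seqs: Mapping[str, str],
    precursor_db: Mapping[str, str],
    min_identity: float = 0.9,
    min_coverage: float = 0.9,
) -> tuple[list[AlignmentHit], int]:
    """Best passing precursor hit per DEL plus the count of DELs with a hit.

    A hit is retained iff identity >= ``min_identity`` and subject coverage
    >= ``min_coverage``.  Exact substring containment short-circuits the
    alignment (identity and coverage 1).
    """
    for name, v in (("min_identity", min_identity), ("min_coverage", min_coverage)):
        if not 0.0 < v <= 1.0:
            raise ValueError(f"{name} must lie in (0, 1]")
    hits: list[AlignmentHit] = []
    if not precursor_db:
        return hits, 0
    for del_id in sorted(del_seqs):
        dseq = del_seqs[del_id].upper()
        best: AlignmentHit | None = None
        for pid in sorted(precursor_db):
            pseq = precursor_db[pid].upper()
            if pseq in dseq:
                hit = AlignmentHit(del_id, pid, 2.0 * len(pseq), 1.0, 1.0)
            else:
                hit = local_align(dseq, pseq, query_id=del_id, subject_id=pid)
            if hit.identity >= min_identity and hit.coverage >= min_coverage:
                if best is None or hit.score > best.score:
                    best = hit
        if best is not None:
            hits.append(best)
    return hits, len({h.query_id for h in hits})


def hits_to_frame(hits: Iterable[AlignmentHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.query_id, h.subject_id, h.score, h.identity, h.coverage) for h in hits],
        columns=["query_id", "subject_id", "score", "identity", "coverage"],
    )


# ---------------------------------------------------------------------------
# core DEL-DEM networks


def build_core_network(
    cis: Iterable[CisPair],
    del_calls: Mapping[str, str],
    dem_calls: Mapping[str, str],
) -> tuple[list[NetworkEdge], list[NetworkEdge], dict]:
    """DEL-DEM edges over cis pairs, split by trend concordance.

    ``del_calls``/``dem_calls`` map ids to ``up``/``down``.  Returns
    (concordant edges, discordant edges, summary) where the summary counts
    the distinct cis genes that are DEMs (the Venn overlap), the
    concordant/discordant pair counts and the distinct entities involved.
    """
    concordant: list[NetworkEdge] = []
    discordant: list[NetworkEdge] = []
    for p in cis:
        dd = del_calls.get(p.lncrna_id)
        md = dem_calls.get(p.gene_id)
        if dd in ("up", "down") and md in ("up", "down"):
            edge = NetworkEdge(p.lncrna_id, p.gene_id, dd, md)
            (concordant if edge.concordant else discordant).append(edge)
    edges = concordant + discordant
    summary = {
        "cis_gene_dem_overlap": len({e.dem_id for e in edges}),
        "concordant_pairs": len(concordant),
        "discordant_pairs": len(discordant),
        "concordant_dels": len({e.del_id for e in concordant}),
        "concordant_genes": len({e.dem_id for e in concordant}),
    }
    return concordant, discordant, summary


def edges_to_frame(edges: Iterable[NetworkEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (e.del_id, e.dem_id, e.del_direction, e.dem_direction, e.concordant)
            for e in edges
        ],
        columns=["del_id", "dem_id", "del_direction", "dem_direction", "concordant"],
    )


def edges_to_graph(edges: Iterable[NetworkEdge]) -> nx.Graph:
    """Bipartite DEL-DEM graph for downstream graph tooling."""
    g = nx.Graph()
    for e in edges:
        g.add_node(e.del_id, kind="DEL", direction=e.del_direction)
        g.add_node(e.dem_id, kind="DEM", direction=e.dem_direction)
        g.add_edge(e.del_id, e.dem_id, concordant=e.concordant)
    return g
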