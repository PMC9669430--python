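"""Independent brute-force reference implementations used to validate the
package's algorithms.  These deliberately use the most naive formulation
available (exhaustive enumeration, direct definitions) and share no code
with the implementations they check."""

from __future__ import annotations

from functools import lru_cache
from math import comb

import numpy as np

_STOPS = ("TAA", "TAG", "TGA")


def brute_longest_orf(seq: str) -> tuple[int, int]:
    """(start 1-based, length) of the longest ATG..stop span by exhaustive
    enumeration over every ATG and every downstream in-frame stop."""
    seq = seq.upper()
    best = (0, 0)
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        for j in range(i + 3, len(seq) - 2, 3):
            if seq[j : j + 3] in _STOPS:
                length = j + 3 - i
                if length > best[1]:
                    best = (i + 1, length)
                break
    return best


def brute_bh(p: np.ndarray) -> np.ndarray:
    """Step-up BH q-values straight from the definition (double loop)."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [
            n * p[order[rank_j - 1]] / rank_j for rank_j in range(rank_i, n + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def brute_local_align_score(
    a: str, b: str, match: float = 2.0, mismatch: float = -1.0, gap: float = -2.0
) -> float:
    """Optimal local alignment score by exhaustive memoised recursion over
    alignment prefixes (any suffix of a vs any suffix of b may start the
    local alignment; score may reset at zero only at the start)."""

    @lru_cache(maxsize=None)
    def ext(i: int, j: int) -> float:
        """Best score of an alignment extending leftwards from a[:i], b[:j],
        allowed to stop anywhere (local)."""
        best = 0.0
        if i > 0 and j > 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            best = max(best, ext(i - 1, j - 1) + s)
        if i > 0:
            best = max(best, ext(i - 1, j) + gap)
        if j > 0:
            best = max(best, ext(i, j - 1) + gap)
        return best

    return max(ext(i, j) for i in range(len(a) + 1) for j in range(len(b) + 1))


def brute_hypergeom_upper(k: int, n_bg: int, big_k: int, n_draw: int) -> float:
    """P(X >= k) for a hypergeometric draw, by direct tail summation of the
    counting formula."""
    total = comb(n_bg, n_draw)
    return sum(
        comb(big_k, x) * comb(n_bg - big_k, n_draw - x)
        for x in range(k, min(big_k, n_draw) + 1)
    ) / total


def brute_cis_pairs(
    lnc_spans: dict[str, tuple[str, int, int]],
    gene_spans: dict[str, tuple[str, int, int]],
    window: int,
) -> set[tuple[str, str, int]]:
    """All-pairs distance computation: (lnc, gene, gap) for every pair that
    overlaps or lies strictly closer than the window."""
    out = set()
    for lid, (lc, ls, le) in lnc_spans.items():
        for gid, (gc, gs, ge) in gene_spans.items():
            if lc != gc:
                continue
            if ls <= ge and gs <= le:
                out.add((lid, gid, 0))
            else:
                gap = (gs - le - 1) if gs > le else (ls - ge - 1)
                if gap < window:
                    out.add((lid, gid, gap))
    return out
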