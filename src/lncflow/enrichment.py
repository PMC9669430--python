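"""Hypergeometric over-representation analysis against GMT-style gene sets.

For a query set of n genes drawn from a background of N genes, of which K
belong to a term, the enrichment p-value is the upper hypergeometric tail
P(X >= k).  Terms are intersected with the background before testing, BH
q-values are computed across the tested terms, and the rich factor k / K
summarises the fraction of a term hit by the query.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .differential import bh_fdr


def hypergeom_enrich(
    query: set[str] | Iterable[str],
    background: set[str] | Iterable[str],
    terms: Mapping[str, tuple[str, list[str]]],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in each term.

    ``terms`` maps term_id -> (name, gene list) as read from a GMT file.
    Terms empty after intersection with the background are skipped (noted
    in the ``skipped`` attribute of the returned frame).  Raises if the
    query is not a subset of the background, listing offenders.
    """
    query = set(query)
    background = set(background)
    stray = sorted(query - background)
    if stray:
        raise ValueError(f"query genes missing from background: {stray[:10]}")

    n_bg = len(background)
    n_query = len(query)
    rows, skipped = [], []
    for term_id in sorted(terms):
        name, genes = terms[term_id]
        term_genes = set(genes) & background
        big_k = len(term_genes)
        if big_k == 0:
            skipped.append(term_id)
            continue
        k = len(term_genes & query)
        p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n_query))
        rows.append((term_id, name, k, big_k, n_query, n_bg, k / big_k, p))
    out = pd.DataFrame(
        rows,
        columns=["term_id", "name", "k", "K", "n", "N", "rich_factor", "p_value"],
    )
    out["q_value"] = bh_fdr(out["p_value"].to_numpy()) if len(out) else []
    out.attrs["skipped"] = skipped
    return out


def top_terms(results: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """Top-k terms by p-value (term_id as deterministic tiebreak), with the
    scatter-table columns used for enrichment dot plots."""
    ranked = results.sort_values(
        ["p_value", "term_id"], kind="mergesort"
    ).head(k)
    return ranked[
        ["term_id", "name", "rich_factor", "q_value", "k", "p_value"]
    ].reset_index(drop=True)
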