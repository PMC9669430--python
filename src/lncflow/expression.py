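"""FPKM quantification and sample-level QC summaries.

Expression is measured as FPKM (fragments per kilobase of transcript per
million mapped reads), which removes the dependence of raw counts on both
transcript length and sequencing depth:

    FPKM_ij = counts_ij * 1e9 / (total_j * length_i)

where ``total_j`` is the column sum of the count matrix.  Sample-sample
agreement is summarised with Pearson correlation on log2(FPKM + 1), and
lncRNA vs mRNA expression levels are compared with a two-sided
Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CountMatrix:
    """Integer read counts, features x samples, with group labels.

    ``lengths`` (bp per feature) enables FPKM computation; ``kinds`` tags
    each feature as ``mRNA``, ``lncRNA`` or ``other`` for the kind-level
    comparisons.
    """

    counts: pd.DataFrame
    groups: dict[str, str]
    lengths: Optional[pd.Series] = None
    kinds: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)
            if self.lengths.isna().any() or (self.lengths < 1).any():
                raise ValueError("every feature needs a length >= 1")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def group_samples(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s in self.counts.columns:
            out.setdefault(self.groups[s], []).append(s)
        return out


@dataclass
class ExpressionMatrix:
    """FPKM values with the feature lengths used to derive them."""

    fpkm: pd.DataFrame
    groups: dict[str, str]
    feature_lengths: pd.Series
    kinds: Optional[pd.Series] = None
    total_counts: pd.Series = field(default=None)  # type: ignore[assignment]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fpkm.columns)


def compute_fpkm(counts: CountMatrix, lengths: Optional[pd.Series] = None) -> ExpressionMatrix:
    """Length- and depth-normalise counts to FPKM.

    Raises ``ValueError`` naming any sample whose total count is zero,
    since FPKM is undefined there.
    """
    if lengths is None:
        lengths = counts.lengths
    if lengths is None:
        raise ValueError("feature lengths are required for FPKM")
    lengths = lengths.reindex(counts.counts.index)
    if lengths.isna().any():
        bad = list(counts.counts.index[lengths.isna()])
        raise ValueError(f"features without a length: {bad[:5]}")
    totals = counts.counts.sum(axis=0)
    zero = [s for s, t in totals.items() if t == 0]
    if zero:
        raise ValueError(f"zero total counts for sample(s): {zero}")
    fpkm = counts.counts * 1e9
    fpkm = fpkm.div(totals, axis=1).div(lengths, axis=0)
    return ExpressionMatrix(
        fpkm=fpkm,
        groups=dict(counts.groups),
        feature_lengths=lengths,
        kinds=counts.kinds,
        total_counts=totals,
    )


def sample_correlation(expr: ExpressionMatrix) -> pd.DataFrame:
    """Pearson correlation between samples on log2(FPKM + 1).

    Samples with zero variance yield NaN against every other sample; the
    diagonal is exactly 1 everywhere.
    """
    logx = np.log2(expr.fpkm.values + 1.0)
    sd = logx.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(logx, rowvar=False)
    r = np.atleast_2d(r)
    r[:, sd == 0] = np.nan
    r[sd == 0, :] = np.nan
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=expr.sample_ids, columns=expr.sample_ids)


def expression_summaries(
    expr: ExpressionMatrix,
    kinds: Optional[Mapping[str, str]] = None,
    n_bins: int = 50,
) -> dict:
    """Density tables, per-kind quartiles and the mRNA-vs-lncRNA contrast.

    Returns a dict with:

    ``density``
        per-sample histogram of log2(FPKM + 1) (long-format DataFrame).
    ``kind_quartiles``
        median and quartiles of mean log2(FPKM + 1) per feature kind.
    ``mwu``
        two-sided Mann-Whitney U of mRNA vs lncRNA mean expression, or
        ``None`` (with a notice) when a kind is absent.
    """
    if kinds is None:
        kinds = expr.kinds
    logx = np.log2(expr.fpkm + 1.0)

    lo = float(np.floor(logx.values.min()))
    hi = float(np.ceil(logx.values.max())) + 1e-9
    edges = np.linspace(lo, hi, n_bins + 1)
    rows = []
    for s in expr.sample_ids:
        hist, _ = np.histogram(logx[s].values, bins=edges)
        mid = 0.5 * (edges[:-1] + edges[1:])
        rows.append(pd.DataFrame({"sample_id": s, "bin_mid": mid, "count": hist}))
    density = pd.concat(rows, ignore_index=True)

    out: dict = {"density": density, "kind_quartiles": None, "mwu": None, "notice": ""}
    if kinds is None:
        out["notice"] = "no feature kinds supplied; kind comparison skipped"
        return out

    kinds = pd.Series(dict(kinds)).reindex(expr.fpkm.index)
    mean_log = logx.mean(axis=1)
    quart = (
        pd.DataFrame({"kind": kinds, "mean_log2_fpkm": mean_log})
        .dropna()
        .groupby("kind")["mean_log2_fpkm"]
        .quantile([0.25, 0.5, 0.75])
        .unstack()
        .rename(columns={0.25: "q25", 0.5: "median", 0.75: "q75"})
    )
    out["kind_quartiles"] = quart

    mrna = mean_log[kinds == "mRNA"]
    lnc = mean_log[kinds == "lncRNA"]
    if len(mrna) == 0 or len(lnc) == 0:
        out["notice"] = "a feature kind has zero members; comparison skipped"
        return out
    u, p = stats.mannwhitneyu(mrna, lnc, alternative="two-sided")
    out["mwu"] = {
        "U": float(u),
        "p_value": float(p),
        "median_mRNA": float(mrna.median()),
        "median_lncRNA": float(lnc.median()),
    }
    return out
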