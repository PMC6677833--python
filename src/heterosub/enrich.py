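"""Cross-classification enrichment between two sample labellings.

Given two categorical labellings of the same cohort (e.g. heterocellular
subtype vs intrinsic subtype), each cell of the cross-tabulation is tested
for over-representation with a one-sided hypergeometric test: for cell
(a, b) with overlap k, the population is the N co-labelled samples, the
"successes" are the row-a margin, and the "draws" are the column-b margin,
so p = P(X >= k).  P values are Benjamini-Hochberg adjusted jointly across
all cells of the matrix.  A Pearson chi-square (no continuity correction)
summarises the overall association.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "StatParams",
    "CrossTab",
    "crosstab",
    "hypergeometric_enrichment",
    "enrichment_matrix",
    "benjamini_hochberg",
    "chi_square_association",
]


@dataclass(frozen=True)
class StatParams:
    """Significance thresholds for enrichment reporting."""

    fdr_threshold: float = 0.05
    alt_fdr_threshold: float = 0.10
    alpha_chi2: float = 0.05

    def __post_init__(self) -> None:
        for name in ("fdr_threshold", "alt_fdr_threshold", "alpha_chi2"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass(frozen=True)
class CrossTab:
    """Contingency table of two labellings over their shared samples."""

    counts: pd.DataFrame  # A labels (rows) x B labels (columns), int counts

    @property
    def row_margins(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())


def crosstab(labels_a: pd.Series | dict, labels_b: pd.Series | dict) -> CrossTab:
    """Cross-tabulate two sample->label mappings over their sample intersection."""
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("the two labellings share no samples")
    logger.info("crosstab over %d shared samples (of %d / %d)", len(shared), len(a), len(b))
    counts = pd.crosstab(a.loc[shared], b.loc[shared])
    counts = counts.sort_index(axis=0).sort_index(axis=1)
    return CrossTab(counts=counts.astype(int))


def hypergeometric_enrichment(t: CrossTab) -> pd.DataFrame:
    """One-sided over-representation p and BH-FDR for every cell.

    Returns a long-format DataFrame with one row per (label_a, label_b)
    cell: overlap count, the two margins, raw p = P(X >= k), FDR (BH over
    all cells jointly), and -log10(FDR) for heatmap display.
    """
    n = t.n
    rows = []
    for a in t.counts.index:
        for b in t.counts.columns:
            k = int(t.counts.loc[a, b])
            ma, mb = int(t.row_margins[a]), int(t.col_margins[b])
            # P(X >= k) for X ~ Hypergeom(N=n, K=ma, n=mb)
            p = float(stats.hypergeom.sf(k - 1, n, ma, mb))
            rows.append({"label_a": a, "label_b": b, "overlap": k,
                         "margin_a": ma, "margin_b": mb, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["fdr"] = benjamini_hochberg(out["p"].to_numpy())
    with np.errstate(divide="ignore"):
        out["neg_log10_fdr"] = -np.log10(out["fdr"])
    return out


def enrichment_matrix(enrichment: pd.DataFrame, value: str = "fdr") -> pd.DataFrame:
    """Pivot a long-format enrichment table to an A-labels x B-labels matrix."""
    return enrichment.pivot(index="label_a", columns="label_b", values=value)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def chi_square_association(t: CrossTab) -> tuple[float, int, float]:
    """Pearson chi-square of independence (no continuity correction).

    Returns (statistic, dof, p).  Warns when any expected count is < 5
    (asymptotic approximation may be poor).
    """
    counts = t.counts.to_numpy()
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("chi-square needs at least a 2x2 table")
    if t.n == 0:
        raise ValueError("empty contingency table")
    res = stats.chi2_contingency(counts, correction=False)
    if (res.expected_freq < 5).any():
        warnings.warn("some expected counts < 5; chi-square approximation may be poor")
    return float(res.statistic), int(res.dof), float(res.pvalue)
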