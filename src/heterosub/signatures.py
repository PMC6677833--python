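"""Per-sample gene-signature scores and group association tests.

A signature score is the arithmetic mean of a sample's log2 expression over
the signature genes present in the matrix (e.g. the expanded immune 18-gene
signature used as an immune-activity readout).  Scores — computed here or
supplied externally (RPPA phenotype scores etc.) — are compared across
subtype groups with the Kruskal-Wallis rank test, with BH-FDR across
multiple scores.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .enrich import benjamini_hochberg
from .io import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureCoverageError",
    "signature_mean_score",
    "score_gene_sets",
    "kruskal_wallis_by_group",
    "kruskal_wallis_table",
]


class SignatureCoverageError(ValueError):
    """Raised when too few signature genes are present in the matrix."""


def signature_mean_score(
    m: pd.DataFrame,
    gene_set: GeneSet,
    min_fraction_present: float = 0.5,
    z_score: bool = False,
) -> pd.Series:
    """Mean expression of a gene set per sample.

    Missing genes are excluded from the mean (no imputation); if fewer than
    ``min_fraction_present`` of the set's genes are present a
    :class:`SignatureCoverageError` is raised naming the absent genes.
    With ``z_score=True`` each gene is standardised across samples first.
    """
    present = [g for g in gene_set.genes if g in m.index]
    missing = [g for g in gene_set.genes if g not in m.index]
    frac = len(present) / len(gene_set.genes)
    if frac < min_fraction_present:
        raise SignatureCoverageError(
            f"signature {gene_set.name!r}: only {len(present)}/{len(gene_set.genes)} "
            f"genes present (< {min_fraction_present:.0%}); missing: {missing}"
        )
    if missing:
        logger.info("signature %s: %d gene(s) absent from matrix: %s",
                    gene_set.name, len(missing), missing)
    x = m.loc[present]
    if z_score:
        sd = x.std(axis=1, ddof=1)
        x = x.sub(x.mean(axis=1), axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    score = x.mean(axis=0)
    score.name = gene_set.name
    return score


def score_gene_sets(
    m: pd.DataFrame,
    gene_sets: list[GeneSet],
    min_fraction_present: float = 0.5,
    z_score: bool = False,
) -> pd.DataFrame:
    """Score several gene sets; returns a samples x signatures table."""
    return pd.DataFrame(
        {s.name: signature_mean_score(m, s, min_fraction_present, z_score) for s in gene_sets}
    )


def kruskal_wallis_by_group(
    scores: pd.Series | dict,
    groups: pd.Series | dict,
) -> tuple[float, int, float]:
    """Kruskal-Wallis H over group labels, computed on the sample intersection.

    Returns (H, dof, p) with tie correction; dof = number of groups - 1.
    The degenerate all-identical-scores case returns H = 0, p = 1 with a
    warning (the chi-square approximation is undefined there).
    """
    scores = pd.Series(scores).astype(float)
    groups = pd.Series(groups).astype(str)
    shared = scores.index.intersection(groups.index)
    scores, groups = scores.loc[shared], groups.loc[shared]
    by_group = [scores[groups == g].to_numpy() for g in groups.unique()]
    by_group = [v for v in by_group if len(v) > 0]
    if len(by_group) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 non-empty groups")
    dof = len(by_group) - 1
    if np.all(scores.to_numpy() == scores.iloc[0]):
        warnings.warn("all scores identical; Kruskal-Wallis degenerate (H = 0)")
        return 0.0, dof, 1.0
    h, p = stats.kruskal(*by_group)
    return float(h), dof, float(p)


def kruskal_wallis_table(
    score_table: pd.DataFrame,
    groups: pd.Series | dict,
) -> pd.DataFrame:
    """Kruskal-Wallis per score column against one grouping, with BH-FDR across scores."""
    rows = []
    for name in score_table.columns:
        h, dof, p = kruskal_wallis_by_group(score_table[name], groups)
        rows.append({"score": name, "H": h, "dof": dof, "p": p})
    out = pd.DataFrame(rows).set_index("score")
    out["fdr"] = benjamini_hochberg(out["p"].to_numpy())
    return out
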