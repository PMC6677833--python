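"""Nearest-centroid subtype classification by Pearson correlation.

A centroid set is a genes x subtypes :class:`pandas.DataFrame` of reference
expression profiles (PAM-style shrunken centroids or any user-supplied
table).  Each sample is correlated (Pearson) with every centroid over the
genes shared between matrix and centroids, then gated into one of three
confidence classes:

``low``
    maximum correlation below ``low_confidence_max_corr`` (default 0.15) —
    the sample resembles no centroid well enough to call;
``mixed``
    the gap between the best and second-best correlation is below
    ``mixed_gap`` (default 0.06) — the sample resembles two subtypes almost
    equally; its *dominant* subtype is the argmax;
``high``
    everything else.

Low confidence takes precedence over mixed.  By default the matrix is
median-centered per gene across the cohort before correlation, matching how
PAM centroids are built from centered data; pass ``center_genes=False`` for
matrices already centered (or to correlate raw values).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierParams",
    "CentroidOverlapError",
    "correlate_to_centroids",
    "call_subtypes",
    "classify",
    "dominant_subtype_table",
    "proportion_report",
]

CONFIDENCE_CLASSES = ("high", "mixed", "low")


class CentroidOverlapError(ValueError):
    """Raised when too few centroid genes are present in the matrix."""


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds for confidence gating.

    low_confidence_max_corr
        Samples whose maximum centroid correlation is below this are called
        low confidence (default 0.15).
    mixed_gap
        Samples whose best-minus-second correlation difference is below
        this are called mixed (default 0.06).
    center_genes
        Subtract each gene's median across samples before correlating
        (default True).
    min_centroid_overlap
        Minimum fraction of centroid genes that must be present in the
        matrix (default 0.80).
    """

    low_confidence_max_corr: float = 0.15
    mixed_gap: float = 0.06
    center_genes: bool = True
    min_centroid_overlap: float = 0.80

    def __post_init__(self) -> None:
        if not -1.0 <= self.low_confidence_max_corr <= 1.0:
            raise ValueError("low_confidence_max_corr must be in [-1, 1]")
        if self.mixed_gap < 0:
            raise ValueError("mixed_gap must be non-negative")
        if not 0.0 < self.min_centroid_overlap <= 1.0:
            raise ValueError("min_centroid_overlap must be in (0, 1]")


def _validate_centroids(centroids: pd.DataFrame, min_subtypes: int = 2) -> None:
    if centroids.shape[1] < min_subtypes:
        raise ValueError(f"centroid set must contain at least {min_subtypes} subtypes")
    if centroids.index.duplicated().any():
        raise ValueError("centroid set has duplicate gene ids")
    if centroids.columns.duplicated().any():
        raise ValueError("centroid set has duplicate subtype names")
    if centroids.isna().any().any():
        raise ValueError("centroid set contains missing values")


def correlate_to_centroids(
    m: pd.DataFrame,
    centroids: pd.DataFrame,
    params: ClassifierParams | None = None,
    min_subtypes: int = 2,
) -> pd.DataFrame:
    """Pearson correlation of every sample with every centroid.

    Returns a samples x subtypes DataFrame.  Samples with zero variance
    over the overlapping genes get NaN correlations (they are gated to low
    confidence downstream).  Classification needs >= 2 centroids;
    single-centroid correlation (used by risk scoring) is allowed via
    ``min_subtypes=1``.

    Raises
    ------
    CentroidOverlapError
        If fewer than ``min_centroid_overlap`` of centroid genes (or fewer
        than 3 genes) are shared with the matrix.
    """
    params = params or ClassifierParams()
    _validate_centroids(centroids, min_subtypes)
    overlap = centroids.index.intersection(m.index)
    frac = len(overlap) / len(centroids.index)
    if frac < params.min_centroid_overlap or len(overlap) < 3:
        raise CentroidOverlapError(
            f"only {len(overlap)}/{len(centroids.index)} centroid genes "
            f"({frac:.1%}) present in matrix; need >= "
            f"{params.min_centroid_overlap:.0%} and >= 3 genes"
        )
    x = m.loc[overlap]
    if params.center_genes:
        x = x.sub(x.median(axis=1), axis=0)
    c = centroids.loc[overlap]

    # fixed memory layout so results are bit-identical whether the matrix
    # arrived in memory or was re-read from disk (BLAS order sensitivity)
    xv = np.ascontiguousarray(x.to_numpy(dtype=float))  # genes x samples
    cv = np.ascontiguousarray(c.to_numpy(dtype=float))  # genes x subtypes
    xc = xv - xv.mean(axis=0)
    cc = cv - cv.mean(axis=0)
    xn = np.sqrt((xc**2).sum(axis=0))
    cn = np.sqrt((cc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (xc.T @ cc) / np.outer(xn, cn)
    corr[~np.isfinite(corr)] = np.nan
    n_degenerate = int(np.isnan(corr).any(axis=1).sum())
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} sample(s) have zero variance over the centroid "
            "gene overlap; their correlations are undefined (gated low)"
        )
    return pd.DataFrame(corr, index=m.columns, columns=centroids.columns)


def call_subtypes(
    correlations: pd.DataFrame,
    params: ClassifierParams | None = None,
) -> pd.DataFrame:
    """Gate per-sample correlation vectors into subtype calls.

    Returns one row per sample with the K correlations plus ``best``,
    ``second``, ``gap``, ``confidence`` and ``dominant`` columns.  Argmax
    ties break to the earlier centroid column.  Samples with undefined
    correlations are called low confidence.
    """
    params = params or ClassifierParams()
    subtypes = list(correlations.columns)
    vals = correlations.to_numpy(dtype=float)
    records = []
    for i, sample in enumerate(correlations.index):
        row = vals[i]
        if np.isnan(row).any():
            records.append((sample, *row, pd.NA, pd.NA, np.nan, "low", pd.NA))
            continue
        order = np.argsort(-row, kind="stable")  # stable: ties keep column order
        best, second = subtypes[order[0]], subtypes[order[1]]
        gap = float(row[order[0]] - row[order[1]])
        if row[order[0]] < params.low_confidence_max_corr:
            conf = "low"
        elif gap < params.mixed_gap:
            conf = "mixed"
        else:
            conf = "high"
        records.append((sample, *row, best, second, gap, conf, best))
    calls = pd.DataFrame(
        records,
        columns=["sample", *subtypes, "best", "second", "gap", "confidence", "dominant"],
    ).set_index("sample")
    return calls


def classify(
    m: pd.DataFrame,
    centroids: pd.DataFrame,
    params: ClassifierParams | None = None,
) -> pd.DataFrame:
    """Correlate and gate in one step (``correlate_to_centroids`` + ``call_subtypes``)."""
    return call_subtypes(correlate_to_centroids(m, centroids, params), params)


def dominant_subtype_table(
    calls: pd.DataFrame,
    include: frozenset[str] | set[str] = frozenset({"high"}),
) -> pd.Series:
    """Map samples in the requested confidence classes to their (dominant) subtype.

    ``include`` may be ``{"high"}`` or ``{"high", "mixed"}``; low-confidence
    samples are never included.
    """
    include = set(include)
    if not include <= {"high", "mixed"}:
        raise ValueError(f"include must be a subset of {{'high', 'mixed'}}, got {include}")
    sel = calls[calls["confidence"].isin(include)]
    if sel.empty:
        warnings.warn("no samples in the requested confidence classes; empty mapping")
    return sel["dominant"].astype(str)


def proportion_report(labels: pd.Series | dict) -> pd.DataFrame:
    """Per-subtype counts, fractions and rounded percentages for a labelling.

    The ``percent`` column is rounded to the nearest integer (the scale on
    which cohort compositions are conventionally reported); ``fraction``
    keeps full precision.  Sorted by descending count.
    """
    labels = pd.Series(labels)
    counts = labels.value_counts()
    total = int(counts.sum())
    rep = pd.DataFrame(
        {
            "count": counts,
            "fraction": counts / total,
            "percent": (100 * counts / total).round().astype(int),
        }
    )
    rep.index.name = "subtype"
    rep.attrs["total_n"] = total
    return rep
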