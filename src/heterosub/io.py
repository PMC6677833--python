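"""Readers, writers and preprocessing for expression matrices, gene sets and clinical tables.

Expression matrices are plain :class:`pandas.DataFrame` objects with feature
(probe or gene) identifiers on the index and sample identifiers on the
columns; values are log2-scale expression.  Two on-disk formats are
supported: tab-delimited (feature id in the first column, sample ids in the
header row) and GCT 1.2.

Gene filtering follows the conventions of log-transformed RSEM data: a
"missing value" is an exact numeric zero, and genes with zeros in more than
``max_zero_fraction`` of samples are dropped rather than imputed.  All
standard deviations use the n-1 denominator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FilterParams",
    "GeneSet",
    "MatrixParseError",
    "read_matrix",
    "write_matrix",
    "filter_zero_heavy_genes",
    "select_variable_genes",
    "collapse_probes",
    "read_gene_sets",
    "write_gene_sets",
    "read_clinical",
    "write_clinical",
]


class MatrixParseError(ValueError):
    """Raised when an expression-matrix file is malformed."""


@dataclass(frozen=True)
class FilterParams:
    """Gene-filtering thresholds.

    max_zero_fraction
        Genes with exact zeros in strictly more than this fraction of
        samples are removed (default 0.30).
    sd_cutoff
        Per-gene sample standard deviation (n-1 denominator) must be
        strictly greater than this to pass variable-gene selection.
    min_centroid_overlap
        Minimum fraction of centroid genes that must be present in a
        matrix for classification (enforced in the classifier).
    """

    max_zero_fraction: float = 0.30
    sd_cutoff: float = 0.0
    min_centroid_overlap: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_zero_fraction <= 1.0:
            raise ValueError("max_zero_fraction must be in [0, 1]")
        if self.sd_cutoff < 0:
            raise ValueError("sd_cutoff must be non-negative")
        if not 0.0 < self.min_centroid_overlap <= 1.0:
            raise ValueError("min_centroid_overlap must be in (0, 1]")


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols (GMT line)."""

    name: str
    description: str = ""
    genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.genes)


def _validate_matrix(df: pd.DataFrame, source: str) -> pd.DataFrame:
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise MatrixParseError(f"{source}: duplicate sample ids {dupes}")
    if df.index.duplicated().any():
        df = _collapse_duplicate_features(df, source)
    non_numeric = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(non_numeric):
        for col in non_numeric:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            if len(bad):
                raise MatrixParseError(
                    f"{source}: non-numeric value {bad.iloc[0]!r} at "
                    f"row {bad.index[0]!r}, column {col!r}"
                )
        df = df.astype(float)
    if df.isna().any().any():
        row, col = next(zip(*np.where(df.isna().to_numpy())))
        raise MatrixParseError(
            f"{source}: missing/NA value at row {df.index[row]!r}, "
            f"column {df.columns[col]!r} (NA tokens are rejected, not imputed)"
        )
    return df.astype(float)


def _collapse_duplicate_features(df: pd.DataFrame, source: str) -> pd.DataFrame:
    """Keep, per duplicated feature id, the row with the highest SD (ties: first)."""
    sds = df.apply(pd.to_numeric, errors="coerce").std(axis=1, ddof=1).to_numpy()
    keep = np.ones(len(df), dtype=bool)
    order = pd.Series(np.arange(len(df)), index=df.index)
    for feat in df.index[df.index.duplicated()].unique():
        rows = np.flatnonzero(df.index == feat)
        best = rows[int(np.argmax(sds[rows]))]
        for r in rows:
            keep[r] = r == best
    n_dropped = int((~keep).sum())
    logger.info("%s: collapsed %d duplicate feature rows (kept highest SD)", source, n_dropped)
    out = df.iloc[keep]
    return out


def read_matrix(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read an expression matrix from ``tsv`` or ``gct`` (GCT 1.2) format.

    Duplicate feature rows are collapsed by keeping the row with the highest
    standard deviation.  NA tokens and non-numeric cells raise
    :class:`MatrixParseError` naming the offending row and column.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False,
                         na_values=[""], float_precision="round_trip")
        df.index = df.index.astype(str)
        return _validate_matrix(df, str(path))
    if format == "gct":
        return _read_gct(path)
    raise ValueError(f"unknown matrix format {format!r}")


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise MatrixParseError(f"{path}: expected GCT version line '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise MatrixParseError(f"{path}: malformed GCT dimension line")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", keep_default_na=False, na_values=[""],
                         float_precision="round_trip")
    if df.shape[0] != n_rows or df.shape[1] - 2 != n_cols:
        raise MatrixParseError(
            f"{path}: GCT declares {n_rows} rows x {n_cols} samples but file "
            f"contains {df.shape[0]} rows x {df.shape[1] - 2} samples"
        )
    df = df.set_index(df.columns[0]).drop(columns=df.columns[1])
    df.index = df.index.astype(str)
    df.index.name = "Name"
    return _validate_matrix(df, str(path))


def write_matrix(m: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    """Write an expression matrix as tab-delimited or GCT 1.2."""
    path = Path(path)
    if format == "tsv":
        m.rename_axis("feature").to_csv(path, sep="\t", float_format="%.17g")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{m.shape[0]}\t{m.shape[1]}\n")
            gct = m.copy()
            gct.insert(0, "Description", "na")
            gct.rename_axis("Name").to_csv(fh, sep="\t", float_format="%.17g")
    else:
        raise ValueError(f"unknown matrix format {format!r}")


def filter_zero_heavy_genes(m: pd.DataFrame, params: FilterParams | None = None) -> pd.DataFrame:
    """Drop genes whose fraction of exact-zero values exceeds the cutoff.

    The inequality is strict: a gene with zeros in exactly
    ``max_zero_fraction`` of samples is retained.
    """
    params = params or FilterParams()
    zero_frac = (m == 0).mean(axis=1)
    keep = zero_frac <= params.max_zero_fraction
    dropped = m.index[~keep]
    if len(dropped):
        logger.info(
            "zero filter (> %.2f): removed %d/%d genes: %s",
            params.max_zero_fraction, len(dropped), len(m),
            ", ".join(map(str, dropped[:20])) + ("..." if len(dropped) > 20 else ""),
        )
    if keep.sum() == 0:
        raise ValueError("zero filter removed every gene; matrix would be empty")
    return m.loc[keep]


def select_variable_genes(m: pd.DataFrame, sd_cutoff: float) -> pd.DataFrame:
    """Retain genes with sample SD (ddof=1) strictly above ``sd_cutoff``.

    Input gene order is preserved.  May return an empty selection (warned).
    """
    if m.shape[1] < 2:
        raise ValueError("variable-gene selection needs at least 2 samples")
    keep = m.std(axis=1, ddof=1) > sd_cutoff
    if keep.sum() == 0:
        warnings.warn(f"no genes pass SD > {sd_cutoff}; returning empty matrix")
    return m.loc[keep]


def collapse_probes(
    m: pd.DataFrame,
    probe_gene_map: Mapping[str, str],
    overrides: Iterable[str] = (),
) -> pd.DataFrame:
    """Collapse probe-level rows to one row per gene.

    For each gene the mapped probe with the highest SD is kept and the row
    relabelled with the gene symbol.  Probes listed in ``overrides`` are
    pinned: they represent their gene regardless of SD (used e.g. to force a
    specific array probe for a gene absent from the annotation).  SD ties
    break to the lexicographically smaller probe id.  Unmapped probes are
    dropped with a logged count.
    """
    probes = [p for p in m.index if p in probe_gene_map]
    if not probes:
        raise ValueError("no probe of the matrix appears in the probe-gene map")
    n_unmapped = len(m) - len(probes)
    if n_unmapped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_unmapped)
    pinned = {probe_gene_map[p]: p for p in overrides if p in probe_gene_map}
    sds = m.std(axis=1, ddof=1)
    chosen: dict[str, str] = {}
    for probe in sorted(probes):  # lexicographic order makes the SD tie-break deterministic
        gene = probe_gene_map[probe]
        if gene in pinned:
            continue
        if gene not in chosen or sds[probe] > sds[chosen[gene]]:
            chosen[gene] = probe
    for gene, probe in pinned.items():
        if probe in m.index:
            chosen[gene] = probe
    genes = sorted(chosen)
    out = m.loc[[chosen[g] for g in genes]]
    out.index = pd.Index(genes, name="gene")
    return out


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: name, description, then member genes, tab-delimited."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3")
            name, desc, members = fields[0], fields[1], [g for g in fields[2:] if g]
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                warnings.warn(f"{path}:{lineno}: gene set {name!r} has duplicate members; de-duplicated")
            sets.append(GeneSet(name=name, description=desc, genes=tuple(unique)))
    if not sets:
        warnings.warn(f"{path}: empty GMT file")
    return sets


def write_gene_sets(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited clinical table.

    Required columns: ``sample``, ``time``, ``event``.  Event values must be
    0 or 1; times must be non-negative.  Any extra columns (treatment,
    auxiliary labels) are preserved verbatim.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    for col in ("sample", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required clinical column {col!r}")
    df["sample"] = df["sample"].astype(str)
    if df["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in clinical table")
    df["time"] = pd.to_numeric(df["time"])
    if (df["time"] < 0).any():
        row = df.index[df["time"] < 0][0]
        raise ValueError(f"{path}: negative survival time at row {row} (sample {df['sample'][row]!r})")
    events = pd.to_numeric(df["event"], errors="coerce")
    bad = df.index[~events.isin([0, 1])]
    if len(bad):
        raise ValueError(
            f"{path}: event value {df['event'][bad[0]]!r} at row {bad[0]} "
            f"(sample {df['sample'][bad[0]]!r}) is not 0/1"
        )
    df["event"] = events.astype(int)
    return df


def write_clinical(clin: pd.DataFrame, path: str | Path) -> None:
    clin.to_csv(path, sep="\t", index=False, float_format="%.17g")
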