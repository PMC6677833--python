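"""Recurrence-risk scores adapted to microarray/RNA-seq log2 data.

Two scores are provided:

* a 21-gene recurrence score (RS): five housekeeping genes' per-sample mean
  is subtracted from sixteen scored genes, group scores are weighted
  averages of member genes, and the unscaled RS is the published linear
  combination of group scores.  The RT-PCR group floors and the 0-100
  clinical rescaling are off by default because log2 microarray values are
  not on the RT-PCR reference-normalized scale; ``apply_group_thresholds``
  enables the floors for rescaled data.
* a centroid-correlation (ROR-style) score: a coefficient-weighted sum of
  Pearson correlations with intrinsic-subtype centroids, with correlations
  computed exactly as in :mod:`heterosub.classify`.

Model coefficients live in editable YAML files (see
``heterosub/models/``); nothing is hard-coded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import ClassifierParams, correlate_to_centroids

__all__ = [
    "GeneGroup",
    "OncotypeModel",
    "RorModel",
    "RiskGroupPolicy",
    "oncotype_reference_normalize",
    "oncotype_recurrence_score",
    "ror_score",
    "assign_risk_groups",
]


@dataclass(frozen=True)
class GeneGroup:
    """A weighted gene group: score = sum(weight * value) / divisor."""

    genes: dict[str, float]
    divisor: float = 1.0
    floor: float | None = None


@dataclass(frozen=True)
class OncotypeModel:
    """The 21-gene RS model: groups, singletons, housekeeping set, coefficients."""

    housekeeping: tuple[str, ...]
    groups: dict[str, GeneGroup]
    group_coefficients: dict[str, float]
    gene_coefficients: dict[str, float]
    pinned_probes: dict[str, str] = field(default_factory=dict)
    apply_group_thresholds: bool = False

    def __post_init__(self) -> None:
        scored = self.scored_genes
        if set(scored) & set(self.housekeeping):
            raise ValueError("scored and housekeeping gene sets must be disjoint")
        seen: set[str] = set()
        for name, grp in self.groups.items():
            dup = seen & set(grp.genes)
            if dup:
                raise ValueError(f"gene(s) {dup} appear in more than one group")
            seen |= set(grp.genes)
        if set(self.group_coefficients) - set(self.groups):
            raise ValueError("coefficient for unknown group")

    @property
    def scored_genes(self) -> tuple[str, ...]:
        out: list[str] = []
        for grp in self.groups.values():
            out.extend(grp.genes)
        out.extend(self.gene_coefficients)
        return tuple(out)

    @classmethod
    def from_yaml(cls, path: str | Path | None = None, **kwargs) -> "OncotypeModel":
        """Load the model from YAML (the packaged Paik-coefficient file by default)."""
        if path is None:
            with resources.files("heterosub").joinpath("models/oncotype.yaml").open() as fh:
                cfg = yaml.safe_load(fh)
        else:
            cfg = yaml.safe_load(Path(path).read_text())
        groups = {
            name: GeneGroup(
                genes={g: float(w) for g, w in spec["genes"].items()},
                divisor=float(spec.get("divisor", 1.0)),
                floor=spec.get("floor"),
            )
            for name, spec in cfg["groups"].items()
        }
        return cls(
            housekeeping=tuple(cfg["housekeeping"]),
            groups=groups,
            group_coefficients={k: float(v) for k, v in cfg["rs_coefficients"]["groups"].items()},
            gene_coefficients={k: float(v) for k, v in cfg["rs_coefficients"].get("genes", {}).items()},
            pinned_probes=dict(cfg.get("pinned_probes", {})),
            **kwargs,
        )

    def with_thresholds(self, enabled: bool = True) -> "OncotypeModel":
        return replace(self, apply_group_thresholds=enabled)


@dataclass(frozen=True)
class RorModel:
    """Centroid-correlation risk model: centroids plus per-subtype coefficients."""

    centroids: pd.DataFrame  # genes x subtypes
    coefficients: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(self.coefficients) - set(self.centroids.columns)
        extra = set(self.centroids.columns) - set(self.coefficients)
        if missing or extra:
            raise ValueError(
                f"coefficient keys must match centroid columns "
                f"(missing centroid: {missing}, missing coefficient: {extra})"
            )

    @classmethod
    def from_yaml(cls, centroids: pd.DataFrame, path: str | Path | None = None) -> "RorModel":
        if path is None:
            with resources.files("heterosub").joinpath("models/ror.yaml").open() as fh:
                cfg = yaml.safe_load(fh)
        else:
            cfg = yaml.safe_load(Path(path).read_text())
        return cls(centroids=centroids, coefficients={k: float(v) for k, v in cfg["coefficients"].items()})


@dataclass(frozen=True)
class RiskGroupPolicy:
    """How scores map to low/intermediate/high risk groups."""

    mode: str = "tertile"  # "tertile" | "fixed"
    thresholds: tuple[float, float] | None = None
    group_names: tuple[str, str, str] = ("low", "intermediate", "high")

    def __post_init__(self) -> None:
        if self.mode not in ("tertile", "fixed"):
            raise ValueError("mode must be 'tertile' or 'fixed'")
        if self.mode == "fixed":
            if self.thresholds is None:
                raise ValueError("fixed mode requires two thresholds")
            t1, t2 = self.thresholds
            if not t1 < t2:
                raise ValueError("fixed thresholds must be strictly increasing")


def oncotype_reference_normalize(m: pd.DataFrame, model: OncotypeModel) -> pd.DataFrame:
    """Subtract each sample's housekeeping-gene mean from the scored genes.

    Requires every housekeeping gene and every scored gene to be present
    (run probe collapse with the model's pinned probes first for
    probe-level arrays).
    """
    missing_hk = [g for g in model.housekeeping if g not in m.index]
    if missing_hk:
        raise ValueError(f"housekeeping gene(s) missing from matrix: {missing_hk}; "
                         "reference normalization undefined")
    missing = [g for g in model.scored_genes if g not in m.index]
    if missing:
        raise ValueError(f"scored gene(s) missing from matrix: {missing}")
    reference = m.loc[list(model.housekeeping)].mean(axis=0)
    return m.loc[list(model.scored_genes)].sub(reference, axis=1)


def oncotype_recurrence_score(normalized: pd.DataFrame, model: OncotypeModel) -> pd.Series:
    """Unscaled RS per sample from a reference-normalized scored-gene table.

    Group score = sum(weight * gene) / divisor; unscaled RS = published
    linear combination of group scores plus singleton-gene terms.  Floors
    apply only when ``model.apply_group_thresholds`` is set.
    """
    rs = pd.Series(0.0, index=normalized.columns, name="recurrence_score")
    for name, grp in model.groups.items():
        score = pd.Series(0.0, index=normalized.columns)
        for gene, w in grp.genes.items():
            score += w * normalized.loc[gene]
        score /= grp.divisor
        if model.apply_group_thresholds and grp.floor is not None:
            score = score.clip(lower=grp.floor)
        rs += model.group_coefficients.get(name, 0.0) * score
    for gene, coef in model.gene_coefficients.items():
        rs += coef * normalized.loc[gene]
    return rs


def ror_score(
    m: pd.DataFrame,
    model: RorModel,
    params: ClassifierParams | None = None,
) -> pd.Series:
    """Coefficient-weighted sum of centroid correlations per sample."""
    corr = correlate_to_centroids(m, model.centroids, params, min_subtypes=1)
    coef = pd.Series(model.coefficients).reindex(corr.columns)
    score = corr.fillna(0.0) @ coef
    score.name = "ror_score"
    return score


def assign_risk_groups(scores: pd.Series, policy: RiskGroupPolicy | None = None) -> pd.Series:
    """Assign each sample to low/intermediate/high risk.

    Tertile mode cuts at the 1/3 and 2/3 quantiles of the cohort's score
    distribution (scores below the first quantile are low, below the second
    intermediate, else high; tied scores share a group).  Fixed mode uses
    the supplied cut points the same way.
    """
    policy = policy or RiskGroupPolicy()
    scores = pd.Series(scores).astype(float)
    low, mid, high = policy.group_names
    if policy.mode == "fixed":
        t1, t2 = policy.thresholds  # type: ignore[misc]
    else:
        if len(scores) < 3:
            raise ValueError("tertile mode needs at least 3 samples")
        if scores.nunique() == 1:
            warnings.warn("all scores identical; every sample assigned to one risk group")
            return pd.Series(low, index=scores.index, name="risk_group")
        t1, t2 = np.quantile(scores.to_numpy(), [1 / 3, 2 / 3])
    groups = pd.Series(
        np.where(scores < t1, low, np.where(scores < t2, mid, high)),
        index=scores.index,
        name="risk_group",
    )
    return groups
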