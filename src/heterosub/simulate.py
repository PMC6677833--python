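"""Synthetic cohort generator with the statistical structure the pipeline assumes.

A cohort is built from K subtype centroids over a common gene universe:
each subtype owns a disjoint block of signature genes elevated by
``effect_size`` (log2 units) over a global baseline.  Samples are *pure*
(own centroid plus i.i.d. Gaussian noise), *mixed* (a convex combination
``w * centroid_a + (1 - w) * centroid_b`` of two distinct centroids plus
noise, with w > 0.5 so the dominant centroid is unique), or *null*
(baseline plus noise, carrying no subtype signal).  Exact zeros can be
injected per gene to exercise zero-fraction filtering, a secondary
categorical labelling copies the true subtype with a configurable
agreement probability, and survival is exponential per subtype with
independent exponential censoring.

Centroids share a per-gene baseline drawn once with SD
``gene_baseline_sd`` — real subtype centroids are strongly positively
correlated because most genes sit at a gene-specific level common to all
subtypes, and it is this shared structure that makes near-even mixtures
genuinely hard to separate.  Null samples carry neither the subtype
signal nor the gene baselines, so they correlate with no centroid.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence(seed).spawn(...)``: child streams, in fixed
order, drive (0) the centroid gene baselines, (1) role assignment and
mixing partners, (2) expression noise, (3) zero injection, (4) secondary
labels, (5) event times, (6) censoring times.  Identical parameters and seed therefore give
bit-identical cohorts, and e.g. changing the zero rate does not perturb
the noise draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import GeneSet, write_clinical, write_gene_sets, write_matrix

__all__ = [
    "DEFAULT_SUBTYPES",
    "GeneratorParams",
    "Cohort",
    "generate_centroids",
    "signature_gene_sets",
    "generate_expression",
    "generate_clinical",
    "generate_cohort",
    "write_cohort",
]

# The five heterocellular (colon-crypt cell type) subtype names, in
# canonical centroid order.
DEFAULT_SUBTYPES = ("stem-like", "inflammatory", "TA", "goblet-like", "enterocyte")

_N_STREAMS = 7
_CENTROIDS, _ROLES, _NOISE, _ZEROS, _LABELS, _EVENTS, _CENSOR = range(_N_STREAMS)


def _default_hazards() -> dict[str, float]:
    # Events per month of follow-up.  The partially differentiated TA
    # subtype carries a 3x hazard, mirroring a poor-prognosis group; the
    # rest share a common favourable rate.
    return {name: (0.03 if name != "TA" else 0.09) for name in DEFAULT_SUBTYPES}


@dataclass(frozen=True)
class GeneratorParams:
    """Cohort-generation parameters (log2 expression units, months for time).

    The defaults describe a five-subtype cohort of 200 samples resembling a
    moderately noisy microarray study: baseline log2 expression 8, signature
    blocks of 20 genes shifted by 2 log2 units (4-fold), unit-SD Gaussian
    noise, 10% mixed and 5% signal-free samples.
    """

    n_genes: int = 500
    n_signature_genes_per_subtype: int = 20
    subtype_names: tuple[str, ...] = DEFAULT_SUBTYPES
    samples_per_subtype: int = 40
    effect_size: float = 2.0
    noise_sd: float = 1.0
    frac_mixed: float = 0.10
    mix_weight: float = 0.60
    frac_null: float = 0.05
    baseline_mean: float = 8.0
    gene_baseline_sd: float = 1.0
    zero_rate_per_gene: float | Mapping[str, float] = 0.0
    secondary_label_agreement: float = 0.70
    hazard_by_subtype: Mapping[str, float] = field(default_factory=_default_hazards)
    censor_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_signature_genes_per_subtype <= 0:
            raise ValueError("gene counts must be positive")
        if len(self.subtype_names) < 2:
            raise ValueError("need at least 2 subtypes")
        if len(set(self.subtype_names)) != len(self.subtype_names):
            raise ValueError("subtype names must be unique")
        if self.samples_per_subtype <= 0:
            raise ValueError("samples_per_subtype must be positive")
        if self.k * self.n_signature_genes_per_subtype > self.n_genes:
            raise ValueError(
                f"{self.k} subtypes x {self.n_signature_genes_per_subtype} signature "
                f"genes exceed n_genes = {self.n_genes}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.gene_baseline_sd < 0:
            raise ValueError("gene_baseline_sd must be non-negative")
        if not (0 <= self.frac_mixed <= 1 and 0 <= self.frac_null <= 1):
            raise ValueError("frac_mixed and frac_null must lie in [0, 1]")
        if self.frac_mixed + self.frac_null > 1:
            raise ValueError("frac_mixed + frac_null must not exceed 1")
        if not 0.5 < self.mix_weight <= 1:
            raise ValueError("mix_weight must lie in (0.5, 1] so the dominant centroid is unique")
        if not 0 <= self.secondary_label_agreement <= 1:
            raise ValueError("secondary_label_agreement must lie in [0, 1]")
        missing = set(self.subtype_names) - set(self.hazard_by_subtype)
        if missing:
            raise ValueError(f"hazard_by_subtype missing subtypes: {missing}")
        if any(h <= 0 for h in self.hazard_by_subtype.values()):
            raise ValueError("hazards must be strictly positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be non-negative")

    @property
    def k(self) -> int:
        return len(self.subtype_names)

    @property
    def n_samples(self) -> int:
        return self.k * self.samples_per_subtype

    def replace(self, **kwargs) -> "GeneratorParams":
        return replace(self, **kwargs)


def _streams(params: GeneratorParams) -> list[np.random.Generator]:
    children = np.random.SeedSequence(params.seed).spawn(_N_STREAMS)
    return [np.random.default_rng(c) for c in children]


def _gene_ids(params: GeneratorParams) -> pd.Index:
    width = len(str(params.n_genes))
    return pd.Index([f"g{i + 1:0{width}d}" for i in range(params.n_genes)], name="gene")


def generate_centroids(params: GeneratorParams) -> pd.DataFrame:
    """Build the K subtype centroids (genes x subtypes), deterministic given the seed.

    Every centroid shares a per-gene baseline ``baseline_mean +
    N(0, gene_baseline_sd)``; subtype k's signature block — genes
    ``[k * B, (k + 1) * B)`` with B = ``n_signature_genes_per_subtype`` —
    additionally sits ``effect_size`` above that baseline.  With
    ``gene_baseline_sd = 0`` the centroids are flat at ``baseline_mean``
    outside their own block.
    """
    genes = _gene_ids(params)
    rng = _streams(params)[_CENTROIDS]
    baseline = params.baseline_mean + (
        rng.normal(0.0, params.gene_baseline_sd, size=params.n_genes)
        if params.gene_baseline_sd > 0
        else np.zeros(params.n_genes)
    )
    values = np.tile(baseline[:, None], (1, params.k))
    b = params.n_signature_genes_per_subtype
    for k in range(params.k):
        values[k * b : (k + 1) * b, k] += params.effect_size
    return pd.DataFrame(values, index=genes, columns=list(params.subtype_names))


def signature_gene_sets(params: GeneratorParams) -> list[GeneSet]:
    """The embedded per-subtype signature blocks as gene sets (GMT-writable)."""
    genes = _gene_ids(params)
    b = params.n_signature_genes_per_subtype
    return [
        GeneSet(
            name=f"SIG_{name}",
            description=f"synthetic signature block of subtype {name}",
            genes=tuple(genes[k * b : (k + 1) * b]),
        )
        for k, name in enumerate(params.subtype_names)
    ]


def generate_expression(
    params: GeneratorParams,
    centroids: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the expression matrix and the per-sample ground truth.

    Returns ``(expression, truth)``: expression is genes x samples; truth
    has one row per sample with ``true_subtype`` (NA for null samples),
    ``role`` (pure/mixed/null), ``mix_partner`` and ``mix_weight`` for
    mixed samples, and the generator seed echoed in ``truth.attrs``.
    """
    if not centroids.index.equals(_gene_ids(params)) or list(centroids.columns) != list(
        params.subtype_names
    ):
        raise ValueError("centroid table does not match the generator's gene/subtype universe")
    rng_roles, rng_noise, rng_zeros = _streams(params)[_ROLES : _ZEROS + 1]
    n = params.n_samples
    width = len(str(n))
    samples = pd.Index([f"s{i + 1:0{width}d}" for i in range(n)], name="sample")
    true_subtype = np.repeat(list(params.subtype_names), params.samples_per_subtype)

    n_null = round(params.frac_null * n)
    n_mixed = round(params.frac_mixed * n)
    special = rng_roles.choice(n, size=n_null + n_mixed, replace=False)
    null_idx = set(special[:n_null].tolist())
    mixed_idx = set(special[n_null:].tolist())

    cvals = centroids.to_numpy()  # genes x K
    col_of = {name: j for j, name in enumerate(params.subtype_names)}
    profiles = np.empty((params.n_genes, n), dtype=float)
    roles = np.empty(n, dtype=object)
    partners = np.full(n, pd.NA, dtype=object)
    weights = np.full(n, np.nan)
    subtype_out = true_subtype.astype(object).copy()
    for i in range(n):
        if i in null_idx:
            roles[i] = "null"
            subtype_out[i] = pd.NA
            profiles[:, i] = params.baseline_mean
        elif i in mixed_idx:
            roles[i] = "mixed"
            others = [s for s in params.subtype_names if s != true_subtype[i]]
            partner = others[rng_roles.integers(len(others))]
            partners[i] = partner
            weights[i] = params.mix_weight
            profiles[:, i] = (
                params.mix_weight * cvals[:, col_of[true_subtype[i]]]
                + (1 - params.mix_weight) * cvals[:, col_of[partner]]
            )
        else:
            roles[i] = "pure"
            profiles[:, i] = cvals[:, col_of[true_subtype[i]]]
    if params.noise_sd > 0:
        profiles = profiles + rng_noise.normal(0.0, params.noise_sd, size=profiles.shape)
    zero_rate = params.zero_rate_per_gene
    if isinstance(zero_rate, Mapping):
        rates = centroids.index.map(lambda g: zero_rate.get(g, 0.0)).to_numpy(dtype=float)
    else:
        rates = np.full(params.n_genes, float(zero_rate))
    if (rates > 0).any():
        mask = rng_zeros.random(profiles.shape) < rates[:, None]
        profiles[mask] = 0.0

    expr = pd.DataFrame(profiles, index=centroids.index, columns=samples)
    truth = pd.DataFrame(
        {
            "true_subtype": subtype_out,
            "role": roles,
            "mix_partner": partners,
            "mix_weight": weights,
        },
        index=samples,
    )
    truth.attrs["seed"] = params.seed
    return expr, truth


def generate_clinical(
    params: GeneratorParams,
    truth: pd.DataFrame,
    treatment: str | int = 1,
) -> pd.DataFrame:
    """Draw survival and labels: observed time, event flag, treatment, secondary label.

    Event times are exponential with the true subtype's hazard (null
    samples use the mean hazard across subtypes); censoring is an
    independent exponential with ``censor_rate`` (rate 0 = no censoring).
    The secondary label copies the true subtype with probability
    ``secondary_label_agreement`` and is uniform over subtypes otherwise
    (always uniform for null samples).  Times, censor indicators and
    secondary labels are also written back onto ``truth``.
    """
    rng_labels, rng_events, rng_censor = _streams(params)[_LABELS:]
    n = len(truth)
    subtype = truth["true_subtype"]
    mean_hazard = float(np.mean([params.hazard_by_subtype[s] for s in params.subtype_names]))
    rates = np.array(
        [params.hazard_by_subtype.get(s, mean_hazard) if pd.notna(s) else mean_hazard
         for s in subtype]
    )
    event_time = rng_events.exponential(1.0 / rates)
    if params.censor_rate > 0:
        censor_time = rng_censor.exponential(1.0 / params.censor_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    copy = rng_labels.random(n) < params.secondary_label_agreement
    uniform = rng_labels.choice(list(params.subtype_names), size=n)
    secondary = np.where(copy & subtype.notna().to_numpy(), subtype.fillna(""), uniform)

    truth["secondary_label"] = secondary
    truth["event_time"] = event_time
    truth["censored"] = 1 - event
    clin = pd.DataFrame(
        {
            "sample": truth.index,
            "time": time,
            "event": event,
            "treatment": treatment,
            "secondary_label": secondary,
        }
    ).reset_index(drop=True)
    return clin


@dataclass(frozen=True)
class Cohort:
    """A fully generated cohort: inputs plus ground truth."""

    params: GeneratorParams
    centroids: pd.DataFrame
    expression: pd.DataFrame
    truth: pd.DataFrame
    clinical: pd.DataFrame
    gene_sets: list[GeneSet]


def generate_cohort(params: GeneratorParams) -> Cohort:
    """Centroids, expression, clinical table and signature sets in one call."""
    centroids = generate_centroids(params)
    expr, truth = generate_expression(params, centroids)
    clin = generate_clinical(params, truth)
    return Cohort(
        params=params,
        centroids=centroids,
        expression=expr,
        truth=truth,
        clinical=clin,
        gene_sets=signature_gene_sets(params),
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, str]:
    """Write every cohort component in the standard formats the readers accept."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression_gct": out / "expression.gct",
        "expression_tsv": out / "expression.tsv",
        "centroids": out / "centroids.tsv",
        "clinical": out / "clinical.tsv",
        "truth": out / "truth.tsv",
        "gene_sets": out / "signatures.gmt",
    }
    write_matrix(cohort.expression, paths["expression_gct"], format="gct")
    write_matrix(cohort.expression, paths["expression_tsv"], format="tsv")
    cohort.centroids.rename_axis("gene").to_csv(paths["centroids"], sep="\t", float_format="%.17g")
    write_clinical(cohort.clinical, paths["clinical"])
    cohort.truth.rename_axis("sample").to_csv(paths["truth"], sep="\t", float_format="%.17g")
    write_gene_sets(cohort.gene_sets, paths["gene_sets"])
    return {k: str(v) for k, v in paths.items()}
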