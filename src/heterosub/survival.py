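"""Kaplan-Meier curves, log-rank tests and Harrell's concordance index.

The clinical table is a DataFrame with columns ``sample``, ``time``
(non-negative observed follow-up), ``event`` (1 = event observed, 0 =
censored) and optional extras (``treatment``, auxiliary labels).  KM
estimation and the k-group log-rank test are delegated to lifelines;
Harrell's C is computed by explicit enumeration of usable pairs so the
usable-pair count and a confidence interval can be reported alongside C.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "KmCurve",
    "ConcordanceResult",
    "kaplan_meier",
    "logrank_test",
    "concordance_index",
    "encode_ordinal_risk",
]


@dataclass(frozen=True)
class KmCurve:
    """Product-limit estimate for one group."""

    group: str
    table: pd.DataFrame  # columns: time, at_risk, events, censored, survival

    @property
    def final_survival(self) -> float:
        return float(self.table["survival"].iloc[-1]) if len(self.table) else 1.0


@dataclass(frozen=True)
class ConcordanceResult:
    """Harrell's C with its usable-pair count and a normal-approximation CI."""

    c: float
    n_usable_pairs: int
    ci_lower: float
    ci_upper: float
    ci_method: str = "normal approximation, SE = sqrt(C(1-C)/n_usable_pairs)"


def _align(clin: pd.DataFrame, mapping: pd.Series | dict) -> pd.DataFrame:
    mapping = pd.Series(mapping)
    sub = clin[clin["sample"].isin(mapping.index)].copy()
    sub["_label"] = mapping.loc[sub["sample"]].to_numpy()
    return sub


def kaplan_meier(clin: pd.DataFrame, groups: pd.Series | dict) -> list[KmCurve]:
    """Product-limit survival estimate per group.

    Censored observations shrink the risk set without introducing steps.
    Groups with no samples in the clinical table are skipped with a warning.
    """
    mapping = pd.Series(groups)
    curves: list[KmCurve] = []
    for label in pd.unique(mapping):
        samples = mapping.index[mapping == label]
        sub = clin[clin["sample"].isin(samples)]
        if sub.empty:
            warnings.warn(f"group {label!r} has no samples in the clinical table; skipped")
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(label))
        ev = kmf.event_table
        table = pd.DataFrame(
            {
                "time": ev.index.to_numpy(dtype=float),
                "at_risk": ev["at_risk"].to_numpy(dtype=int),
                "events": ev["observed"].to_numpy(dtype=int),
                "censored": ev["censored"].to_numpy(dtype=int),
                "survival": kmf.survival_function_.iloc[:, 0].reindex(ev.index).to_numpy(),
            }
        ).reset_index(drop=True)
        curves.append(KmCurve(group=str(label), table=table))
    return curves


def logrank_test(clin: pd.DataFrame, groups: pd.Series | dict) -> tuple[float, int, float]:
    """k-group log-rank chi-square: returns (statistic, dof, p); dof = k - 1."""
    sub = _align(clin, groups)
    labels = sub["_label"].unique()
    if len(labels) < 2:
        raise ValueError("log-rank test needs at least 2 non-empty groups")
    res = multivariate_logrank_test(sub["time"], sub["_label"], sub["event"])
    return float(res.test_statistic), len(labels) - 1, float(res.p_value)


def concordance_index(
    clin: pd.DataFrame,
    risk: pd.Series | dict,
    alpha: float = 0.05,
) -> ConcordanceResult:
    """Harrell's C between a per-sample risk and observed survival.

    A pair is usable iff the shorter observed time carries an event and the
    times differ, or the times tie with discordant event status.  A usable
    pair is concordant when the sample that failed first has the higher
    risk; tied risks count 0.5.  Higher risk is expected to mean shorter
    survival, so C = 1 is perfect anti-ordering of risk and time.

    The confidence interval is a normal approximation using the
    binomial-type standard error sqrt(C(1-C)/m) over the m usable pairs
    (pairs are not independent, so this is an approximation; the method is
    recorded on the result).
    """
    sub = _align(clin, risk)
    if len(sub) < 2:
        raise ValueError("concordance needs risk values for at least 2 samples")
    t = sub["time"].to_numpy(dtype=float)
    e = sub["event"].to_numpy(dtype=int)
    r = sub["_label"].to_numpy(dtype=float)
    usable = 0
    score = 0.0
    for i, j in itertools.combinations(range(len(sub)), 2):
        if t[i] == t[j]:
            if e[i] == e[j]:
                continue  # tied times, same status: not usable
            first, other = (i, j) if e[i] == 1 else (j, i)
        elif t[i] < t[j]:
            if e[i] != 1:
                continue  # earlier time censored: ordering unknown
            first, other = i, j
        else:
            if e[j] != 1:
                continue
            first, other = j, i
        usable += 1
        if r[first] > r[other]:
            score += 1.0
        elif r[first] == r[other]:
            score += 0.5
    if usable == 0:
        raise ValueError("no usable pairs (all times tied or all early times censored)")
    c = score / usable
    from scipy import stats

    z = stats.norm.ppf(1 - alpha / 2)
    se = np.sqrt(max(c * (1 - c), 0.0) / usable)
    return ConcordanceResult(
        c=float(c),
        n_usable_pairs=usable,
        ci_lower=float(max(0.0, c - z * se)),
        ci_upper=float(min(1.0, c + z * se)),
    )


def encode_ordinal_risk(labels: pd.Series | dict, order: list[str]) -> pd.Series:
    """Map ordered categorical risk labels (e.g. low<intermediate<high) to integer ranks."""
    labels = pd.Series(labels).astype(str)
    unknown = set(labels.unique()) - set(order)
    if unknown:
        raise ValueError(f"labels {unknown} missing from the supplied order {order}")
    rank = {lab: i for i, lab in enumerate(order)}
    return labels.map(rank).astype(float)
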