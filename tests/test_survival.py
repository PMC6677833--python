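import itertools

import numpy as np
import pandas as pd
import pytest
from lifelines.utils import concordance_index as lifelines_c

from heterosub import survival as surv


def clin(times, events, samples=None) -> pd.DataFrame:
    samples = samples or [f"s{i}" for i in range(len(times))]
    return pd.DataFrame({"sample": samples, "time": times, "event": events})


def logrank_oracle_two_groups(t1, e1, t2, e2):
    """Brute-force two-group log-rank chi-square from explicit risk tables."""
    events = sorted({t for t, e in zip(list(t1) + list(t2), list(e1) + list(e2)) if e == 1})
    o_minus_e = 0.0
    var = 0.0
    for t in events:
        n1 = sum(x >= t for x in t1)
        n2 = sum(x >= t for x in t2)
        d1 = sum(x == t and e == 1 for x, e in zip(t1, e1))
        d2 = sum(x == t and e == 1 for x, e in zip(t2, e2))
        n, d = n1 + n2, d1 + d2
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestKaplanMeier:
    def test_three_events_no_censoring_product_limit(self):
        curves = surv.kaplan_meier(clin([1, 2, 3], [1, 1, 1]),
                                   pd.Series("g", index=["s0", "s1", "s2"]))
        table = curves[0].table
        steps = table[table["events"] > 0]["survival"].tolist()
        np.testing.assert_allclose(steps, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_flat_at_one(self):
        curves = surv.kaplan_meier(clin([1, 2, 3], [0, 0, 0]),
                                   pd.Series("g", index=["s0", "s1", "s2"]))
        assert (curves[0].table["survival"] == 1.0).all()

    def test_single_sample_steps_to_zero_at_event(self):
        curves = surv.kaplan_meier(clin([5], [1]), pd.Series("g", index=["s0"]))
        table = curves[0].table
        assert table.loc[table["time"] == 5.0, "survival"].iloc[0] == 0.0

    def test_censoring_shrinks_risk_set_without_step(self):
        # events at 1 and 3, censor at 2: S = 3/4 after t=1, then 3/4 * 1/2 after t=3
        curves = surv.kaplan_meier(clin([1, 2, 3, 4], [1, 0, 1, 0]),
                                   pd.Series("g", index=[f"s{i}" for i in range(4)]))
        table = curves[0].table.set_index("time")
        assert table.loc[1.0, "survival"] == pytest.approx(3 / 4)
        assert table.loc[2.0, "survival"] == pytest.approx(3 / 4)  # no step at censor
        assert table.loc[3.0, "survival"] == pytest.approx(3 / 8)

    def test_empty_group_skipped_with_warning(self):
        groups = pd.Series({"s0": "a", "missing": "b"})
        with pytest.warns(UserWarning, match="'b'"):
            curves = surv.kaplan_meier(clin([1], [1]), groups)
        assert [c.group for c in curves] == ["a"]

    def test_survival_non_increasing_from_one(self, default_cohort):
        curves = surv.kaplan_meier(default_cohort.clinical,
                                   default_cohort.truth["true_subtype"].dropna())
        for c in curves:
            s = c.table["survival"].to_numpy()
            assert s[0] <= 1.0 and (np.diff(s) <= 1e-12).all()


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        times, events = [1, 2, 3, 4], [1, 1, 0, 1]
        c = clin(times + times, events + events,
                 samples=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)])
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=c["sample"])
        stat, dof, p = surv.logrank_test(c, groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert dof == 1

    def test_matches_brute_force_risk_table_evaluation(self):
        t1, e1 = [1.0, 2.0], [1, 1]
        t2, e2 = [10.0, 11.0], [1, 1]
        c = clin(t1 + t2, e1 + e2, samples=["a0", "a1", "b0", "b1"])
        groups = pd.Series(["A", "A", "B", "B"], index=c["sample"])
        stat, dof, _ = surv.logrank_test(c, groups)
        assert stat == pytest.approx(logrank_oracle_two_groups(t1, e1, t2, e2), rel=1e-9)

    def test_symmetric_under_group_renaming(self):
        rng = np.random.default_rng(0)
        c = clin(rng.exponential(5, 30).tolist(), rng.integers(0, 2, 30).tolist())
        g = pd.Series(rng.choice(["A", "B"], 30), index=c["sample"])
        s1, _, _ = surv.logrank_test(c, g)
        s2, _, _ = surv.logrank_test(c, g.map({"A": "B", "B": "A"}))
        assert s1 == pytest.approx(s2)

    def test_single_group_error(self):
        c = clin([1, 2], [1, 1])
        with pytest.raises(ValueError):
            surv.logrank_test(c, pd.Series(["A", "A"], index=c["sample"]))


def concordance_oracle(times, events, risks):
    """Exhaustive usable-pair enumeration, independent of the implementation."""
    num, den = 0.0, 0
    for i, j in itertools.combinations(range(len(times)), 2):
        pair = None
        if times[i] != times[j]:
            first, other = (i, j) if times[i] < times[j] else (j, i)
            if events[first] == 1:
                pair = (first, other)
        elif events[i] != events[j]:
            pair = (i, j) if events[i] == 1 else (j, i)
        if pair is None:
            continue
        den += 1
        if risks[pair[0]] > risks[pair[1]]:
            num += 1
        elif risks[pair[0]] == risks[pair[1]]:
            num += 0.5
    return num / den, den


class TestConcordance:
    def test_perfect_anti_ordering_gives_one(self):
        c = clin([1, 2, 3, 4], [1, 1, 1, 1])
        risk = pd.Series([4.0, 3.0, 2.0, 1.0], index=c["sample"])
        res = surv.concordance_index(c, risk)
        assert res.c == pytest.approx(1.0)
        assert res.n_usable_pairs == 6

    def test_constant_risk_gives_half(self):
        c = clin([1, 2, 3, 4], [1, 1, 1, 1])
        res = surv.concordance_index(c, pd.Series(1.0, index=c["sample"]))
        assert res.c == pytest.approx(0.5)

    def test_censored_fixture_matches_exhaustive_enumeration(self):
        times, events = [2.0, 4.0, 4.0, 7.0], [1, 0, 1, 1]
        risks = [3.0, 1.0, 2.0, 2.0]
        c = clin(times, events)
        res = surv.concordance_index(c, pd.Series(risks, index=c["sample"]))
        expected_c, expected_n = concordance_oracle(times, events, risks)
        assert res.c == pytest.approx(expected_c)
        assert res.n_usable_pairs == expected_n

    def test_random_cohort_matches_oracle_and_lifelines(self):
        rng = np.random.default_rng(21)
        times = rng.exponential(10, 40).tolist()  # continuous: no ties
        events = rng.integers(0, 2, 40).tolist()
        risks = rng.normal(size=40).tolist()
        c = clin(times, events)
        res = surv.concordance_index(c, pd.Series(risks, index=c["sample"]))
        oc, on = concordance_oracle(times, events, risks)
        assert res.c == pytest.approx(oc)
        # lifelines scores predictions where higher = longer survival
        assert res.c == pytest.approx(lifelines_c(times, [-r for r in risks], events))

    def test_negated_risk_complements_c_without_ties(self):
        rng = np.random.default_rng(9)
        c = clin(rng.exponential(5, 25).tolist(), rng.integers(0, 2, 25).tolist())
        risk = pd.Series(rng.normal(size=25), index=c["sample"])
        c_pos = surv.concordance_index(c, risk).c
        c_neg = surv.concordance_index(c, -risk).c
        assert c_pos + c_neg == pytest.approx(1.0)

    def test_ci_brackets_c(self):
        c = clin([1, 2, 3, 4, 5], [1, 1, 0, 1, 1])
        res = surv.concordance_index(c, pd.Series([5, 4, 3, 2, 1.0], index=c["sample"]))
        assert res.ci_lower <= res.c <= res.ci_upper

    def test_no_usable_pairs_error(self):
        c = clin([5.0, 5.0], [1, 1])
        with pytest.raises(ValueError, match="usable"):
            surv.concordance_index(c, pd.Series([1.0, 2.0], index=c["sample"]))


class TestOrdinalEncoding:
    def test_order_respected(self):
        labels = pd.Series({"s1": "low", "s2": "high", "s3": "intermediate"})
        enc = surv.encode_ordinal_risk(labels, ["low", "intermediate", "high"])
        assert enc.tolist() == [0.0, 2.0, 1.0]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="order"):
            surv.encode_ordinal_risk(pd.Series({"s1": "weird"}), ["low", "high"])
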