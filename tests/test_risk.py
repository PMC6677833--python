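import numpy as np
import pandas as pd
import pytest

from heterosub import risk
from heterosub.classify import ClassifierParams
from tests.conftest import pearson_brute

RAW = ClassifierParams(center_genes=False)


@pytest.fixture(scope="module")
def model() -> risk.OncotypeModel:
    return risk.OncotypeModel.from_yaml()


def _matrix(model, fill=None, rng_seed=0, n_samples=3):
    """A matrix covering all 21 model genes."""
    genes = list(model.scored_genes) + list(model.housekeeping)
    if fill is not None:
        vals = np.full((len(genes), n_samples), float(fill))
    else:
        vals = np.random.default_rng(rng_seed).normal(8, 2, (len(genes), n_samples))
    return pd.DataFrame(vals, index=genes, columns=[f"s{i}" for i in range(n_samples)])


class TestModelConfig:
    def test_sixteen_scored_and_five_housekeeping_genes(self, model):
        assert len(model.scored_genes) == 16
        assert len(model.housekeeping) == 5
        assert not set(model.scored_genes) & set(model.housekeeping)

    def test_cd68_probe_pinned(self, model):
        assert model.pinned_probes["CD68"] == "203507_at"

    def test_each_scored_gene_in_exactly_one_group(self, model):
        grouped = [g for grp in model.groups.values() for g in grp.genes]
        assert len(grouped) == len(set(grouped))


class TestReferenceNormalize:
    def test_all_equal_input_normalizes_to_zero(self, model):
        norm = risk.oncotype_reference_normalize(_matrix(model, fill=7.0), model)
        assert (norm == 0.0).all().all()

    def test_per_sample_constant_shift_cancels(self, model):
        m = _matrix(model)
        shifted = m + pd.Series([1.0, -2.0, 0.5], index=m.columns)
        a = risk.oncotype_reference_normalize(m, model)
        b = risk.oncotype_reference_normalize(shifted, model)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_housekeeping_mean_subtraction_value(self, model):
        m = _matrix(model, fill=0.0, n_samples=1)
        m.loc[list(model.housekeeping), "s0"] = [1.0, 2.0, 3.0, 4.0, 5.0]
        m.loc["GRB7", "s0"] = 7.0
        norm = risk.oncotype_reference_normalize(m, model)
        assert norm.loc["GRB7", "s0"] == pytest.approx(4.0)  # 7 - mean(1..5)

    def test_missing_housekeeping_gene_is_an_error(self, model):
        m = _matrix(model).drop(index="ACTB")
        with pytest.raises(ValueError, match="ACTB"):
            risk.oncotype_reference_normalize(m, model)


class TestRecurrenceScore:
    def test_all_zero_normalized_gives_zero_rs(self, model):
        norm = risk.oncotype_reference_normalize(_matrix(model, fill=3.0), model)
        rs = risk.oncotype_recurrence_score(norm, model)
        np.testing.assert_allclose(rs.to_numpy(), 0.0, atol=1e-12)

    def test_homogeneity_without_thresholds(self, model):
        norm = risk.oncotype_reference_normalize(_matrix(model, rng_seed=3), model)
        rs1 = risk.oncotype_recurrence_score(norm, model)
        rs2 = risk.oncotype_recurrence_score(2.0 * norm, model)
        np.testing.assert_allclose(rs2.to_numpy(), 2.0 * rs1.to_numpy())

    def test_matches_spreadsheet_style_hand_evaluation(self, model):
        norm = risk.oncotype_reference_normalize(_matrix(model, rng_seed=9), model)
        rs = risk.oncotype_recurrence_score(norm, model)
        for s in norm.columns:
            expected = 0.0
            for gname, grp in model.groups.items():
                gscore = sum(w * norm.loc[g, s] for g, w in grp.genes.items()) / grp.divisor
                expected += model.group_coefficients[gname] * gscore
            for g, coef in model.gene_coefficients.items():
                expected += coef * norm.loc[g, s]
            assert rs[s] == pytest.approx(expected, rel=1e-10)

    def test_rs_invariant_to_per_sample_shift_of_all_21_genes(self, model):
        m = _matrix(model, rng_seed=11)
        rs1 = risk.oncotype_recurrence_score(risk.oncotype_reference_normalize(m, model), model)
        rs2 = risk.oncotype_recurrence_score(
            risk.oncotype_reference_normalize(m + 4.2, model), model)
        np.testing.assert_allclose(rs1.to_numpy(), rs2.to_numpy(), atol=1e-10)

    def test_group_floors_only_apply_when_enabled(self, model):
        norm = risk.oncotype_reference_normalize(_matrix(model, fill=5.0), model)
        rs_off = risk.oncotype_recurrence_score(norm, model)
        rs_on = risk.oncotype_recurrence_score(norm, model.with_thresholds())
        # all-zero normalized values: floors (8 and 6.5) bind when enabled
        assert (rs_off == 0).all()
        expected = 0.47 * 8.0 + 1.04 * 6.5
        np.testing.assert_allclose(rs_on.to_numpy(), expected)


class TestRorScore:
    def _centroids(self):
        c1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        c2 = np.array([2.0, 1.0, 5.0, 3.0, 4.0])
        return pd.DataFrame({"A": c1, "B": c2}, index=[f"g{i}" for i in range(5)])

    def test_zero_coefficients_give_zero_score(self):
        c = self._centroids()
        m = pd.DataFrame({"s": c["A"]})
        model = risk.RorModel(centroids=c, coefficients={"A": 0.0, "B": 0.0})
        assert risk.ror_score(m, model, RAW)["s"] == pytest.approx(0.0)

    def test_sample_equal_to_single_centroid(self):
        c = self._centroids()[["A"]]
        m = pd.DataFrame({"s": c["A"]})
        model = risk.RorModel(centroids=c, coefficients={"A": 1.0})
        assert risk.ror_score(m, model, RAW)["s"] == pytest.approx(1.0)

    def test_matches_brute_force_correlation_combination(self):
        c = self._centroids()
        m = pd.DataFrame({"s": c["A"]})
        model = risk.RorModel(centroids=c, coefficients={"A": 0.5, "B": -0.3})
        expected = 0.5 * 1.0 - 0.3 * pearson_brute(c["A"], c["B"])
        assert risk.ror_score(m, model, RAW)["s"] == pytest.approx(expected, abs=1e-12)

    def test_linear_in_coefficients(self):
        c = self._centroids()
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.normal(3, 1, (5, 4)), index=c.index,
                         columns=[f"s{i}" for i in range(4)])
        s_a = risk.ror_score(m, risk.RorModel(c, {"A": 1.0, "B": 0.0}), RAW)
        s_b = risk.ror_score(m, risk.RorModel(c, {"A": 0.0, "B": 1.0}), RAW)
        s_mix = risk.ror_score(m, risk.RorModel(c, {"A": 2.0, "B": -0.5}), RAW)
        np.testing.assert_allclose(s_mix.to_numpy(), (2.0 * s_a - 0.5 * s_b).to_numpy(), atol=1e-12)

    def test_coefficient_centroid_mismatch_rejected(self):
        c = self._centroids()
        with pytest.raises(ValueError, match="match"):
            risk.RorModel(centroids=c, coefficients={"A": 1.0})

    def test_packaged_ror_coefficients_load(self):
        c = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 4)),
                         index=[f"g{i}" for i in range(10)],
                         columns=["Basal", "Her2", "LumA", "LumB"])
        model = risk.RorModel.from_yaml(c)
        assert model.coefficients["LumA"] == pytest.approx(-0.34)


class TestRiskGroups:
    def test_nine_distinct_scores_split_three_per_tertile(self):
        scores = pd.Series(np.arange(1.0, 10.0), index=[f"s{i}" for i in range(9)])
        groups = risk.assign_risk_groups(scores)
        assert groups.value_counts().tolist() == [3, 3, 3]
        # brute-force: sorted order must be low*3, intermediate*3, high*3
        ordered = groups[scores.sort_values().index].tolist()
        assert ordered == ["low"] * 3 + ["intermediate"] * 3 + ["high"] * 3

    def test_fixed_thresholds(self):
        scores = pd.Series({"a": 10.0, "b": 25.0, "c": 40.0})
        policy = risk.RiskGroupPolicy(mode="fixed", thresholds=(18.0, 31.0))
        groups = risk.assign_risk_groups(scores, policy)
        assert groups.tolist() == ["low", "intermediate", "high"]

    def test_all_identical_scores_single_group_with_warning(self):
        scores = pd.Series(5.0, index=[f"s{i}" for i in range(6)])
        with pytest.warns(UserWarning, match="identical"):
            groups = risk.assign_risk_groups(scores)
        assert groups.nunique() == 1

    def test_unordered_fixed_thresholds_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            risk.RiskGroupPolicy(mode="fixed", thresholds=(31.0, 18.0))

    def test_assignment_partitions_cohort(self):
        rng = np.random.default_rng(12)
        scores = pd.Series(rng.normal(size=50), index=[f"s{i}" for i in range(50)])
        groups = risk.assign_risk_groups(scores)
        assert len(groups) == 50 and groups.isin(["low", "intermediate", "high"]).all()
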