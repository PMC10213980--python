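"""Normalization, differential abundance, meta-analysis, persistence filter."""

import logging

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import persistnet as pn
from persistnet.diffmeta import direction_consistency


def make_cohort(seed, n_case=50, n_control=50, n_features=20, effect=None, cohort="c"):
    """Standard-normal cohort with optional per-feature additive case effects."""
    rng = np.random.default_rng(seed)
    n = n_case + n_control
    vals = rng.standard_normal((n_features, n))
    if effect is not None:
        vals[:, :n_case] += np.asarray(effect)[:, None]
    samples = [f"{cohort}_s{i}" for i in range(n)]
    X = pn.ExpressionMatrix([f"F{i:03d}" for i in range(n_features)], samples, vals, cohort)
    tdf = pd.DataFrame(
        {
            "group": ["case"] * n_case + ["control"] * n_control,
            "age": rng.normal(35, 8, n),
            "BMI": rng.normal(27, 4, n),
        },
        index=samples,
    )
    return X, pn.TraitTable(tdf)


class TestMedianNormalize:
    def test_equalizes_sample_medians(self, default_fixture):
        _, expressions, _, _ = default_fixture
        Xn = pn.median_normalize(expressions[0])
        med = np.median(Xn.values, axis=0)
        assert np.allclose(med, med[0])

    def test_removes_planted_scale_jitter(self, default_fixture):
        _, expressions, _, _ = default_fixture
        X = expressions[0]
        Xn = pn.median_normalize(X)
        raw_spread = np.median(X.values, axis=0).std()
        norm_spread = np.median(Xn.values, axis=0).std()
        assert norm_spread < 1e-9 < raw_spread

    def test_already_normalized_is_fixed_point(self, default_fixture):
        _, expressions, _, _ = default_fixture
        Xn = pn.median_normalize(expressions[0])
        Xnn = pn.median_normalize(Xn)
        assert np.allclose(Xn.values, Xnn.values)

    def test_log2_transform(self):
        X = pn.ExpressionMatrix(
            ["a", "b"], ["s0", "s1"], np.array([[4.0, 8.0], [16.0, 32.0]])
        )
        Xn = pn.median_normalize(X, log2=True)
        assert np.all(np.isfinite(Xn.values))
        # sample medians equalized before the log
        assert np.allclose(np.median(2.0**Xn.values, axis=0), np.median(2.0**Xn.values[:, 0]))

    def test_nonpositive_median_rejected(self):
        X = pn.ExpressionMatrix(["a"], ["s0", "s1"], np.array([[1.0, -2.0]]))
        with pytest.raises(ValueError, match="positive"):
            pn.median_normalize(X)


class TestDifferentialExpression:
    def test_planted_effect_recovered(self):
        effect = np.zeros(20)
        effect[0] = 1.0
        X, traits = make_cohort(0, n_case=200, n_control=200, effect=effect)
        res = pn.differential_expression(X, traits)
        row = res.table.iloc[0]
        # coefficient is on the standardized scale: d = 1 SD shift over
        # sqrt(1 + d^2/4) total SD ~ 0.89
        assert row["p"] < 1e-10
        assert 0.6 < row["d"] < 1.2
        assert np.sign(row["coef"]) == 1

    def test_null_p_uniform(self):
        X, traits = make_cohort(1, n_features=400)
        res = pn.differential_expression(X, traits)
        ks = stats.kstest(res.table["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        X, traits = make_cohort(2, n_case=40, n_control=40, n_features=5)
        res = pn.differential_expression(X, traits, covariates=["age", "BMI"])
        y = X.values[3]
        y = (y - y.mean()) / y.std(ddof=1)
        D = np.column_stack(
            [
                np.ones(80),
                traits.group_indicator().to_numpy(),
                traits.data["age"].to_numpy(),
                traits.data["BMI"].to_numpy(),
            ]
        )
        fit = sm.OLS(y, D).fit()
        assert res.table.iloc[3]["coef"] == pytest.approx(fit.params[1], abs=1e-10)
        assert res.table.iloc[3]["se"] == pytest.approx(fit.bse[1], abs=1e-10)
        assert res.table.iloc[3]["p"] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_hedges_correction_shrinks_d(self):
        effect = np.full(5, 0.8)
        X, traits = make_cohort(3, n_case=10, n_control=10, n_features=5, effect=effect)
        plain = pn.differential_expression(X, traits)
        hedges = pn.differential_expression(X, traits, hedges_correction=True)
        factor = 1.0 - 3.0 / (4.0 * 20 - 9.0)
        assert np.allclose(hedges.table["d"], plain.table["d"] * factor)

    def test_confounded_covariate_flagged(self):
        X, traits = make_cohort(4)
        tdf = traits.data.copy()
        tdf["dup"] = traits.group_indicator()  # identical to the group column
        with pytest.raises(ValueError, match="collinear"):
            pn.differential_expression(X, pn.TraitTable(tdf), covariates=["dup"])

    def test_too_few_per_group_rejected(self):
        X, traits = make_cohort(5, n_case=2, n_control=50)
        with pytest.raises(ValueError, match="3 samples"):
            pn.differential_expression(X, traits)


class TestStouffer:
    def test_printed_two_cohort_example(self):
        # Z = (sqrt(100)*1.96 + sqrt(50)*1.64)/sqrt(150) = 2.5475...
        z, p = pn.stouffer_combine(
            p=np.array([0.05, 0.10]), sign=np.array([1, 1]), n=np.array([100, 50])
        )
        w = np.sqrt([100, 50])
        zk = stats.norm.isf(np.array([0.05, 0.10]) / 2)
        expected = (w * zk).sum() / np.sqrt((w**2).sum())
        assert z == pytest.approx(expected, abs=1e-12)
        assert p == pytest.approx(2 * stats.norm.sf(abs(expected)), rel=1e-12)

    def test_opposite_signs_cancel(self):
        z, p = pn.stouffer_combine(
            p=np.array([0.01, 0.01]), sign=np.array([1, -1]), n=np.array([80, 80])
        )
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_single_cohort_identity(self):
        z, p = pn.stouffer_combine(np.array([0.04]), np.array([-1]), np.array([60]))
        assert z == pytest.approx(-stats.norm.isf(0.02), abs=1e-12)
        assert p == pytest.approx(0.04, rel=1e-10)

    def test_zero_p_clamped_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            z, p = pn.stouffer_combine(np.array([0.0, 0.5]), np.array([1, 1]), np.array([50, 50]))
        assert np.isfinite(z)
        assert any("clamped" in r.message for r in caplog.records)

    def test_invalid_sign_rejected(self):
        with pytest.raises(ValueError, match="sign"):
            pn.stouffer_combine(np.array([0.5]), np.array([0]), np.array([10]))


class TestAdjust:
    def test_bh_matches_hand_computation(self):
        p = np.array([0.01, 0.04, 0.03, 0.005])
        q = pn.adjust_pvalues(p, "BH")
        # sorted p: .005,.01,.03,.04 -> q: .02,.02,.04,.04
        assert np.allclose(q, [0.02, 0.04, 0.04, 0.02])

    def test_by_equals_bh_times_harmonic(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        c = np.sum(1.0 / np.arange(1, 51))
        assert np.allclose(
            pn.adjust_pvalues(p, "BY"), np.minimum(1.0, pn.adjust_pvalues(p, "BH") * c)
        )

    def test_bonferroni(self):
        assert np.allclose(
            pn.adjust_pvalues(np.array([0.01, 0.2]), "bonferroni"), [0.02, 0.4]
        )

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            pn.adjust_pvalues(np.array([0.5]), "holmes")

    def test_empty_input_passthrough(self):
        assert len(pn.adjust_pvalues(np.array([]), "BH")) == 0


class TestRandomEffects:
    def test_homogeneous_studies_reduce_to_fixed_effects(self):
        d = np.array([0.5, 0.5, 0.5])
        v = np.array([0.2, 0.2, 0.2])
        res = pn.random_effects_meta(d, v)
        assert res["d"] == pytest.approx(0.5)
        assert res["tau2"] == 0.0
        assert res["Q"] == pytest.approx(0.0)
        assert res["se"] == pytest.approx(np.sqrt(0.2 / 3))

    def test_heterogeneity_inflates_tau2_and_se(self):
        d_het = np.array([0.9, 0.0, -0.3, 1.2])
        v = np.full(4, 0.05)
        het = pn.random_effects_meta(d_het, v)
        hom = pn.random_effects_meta(np.full(4, 0.45), v)
        assert het["tau2"] > 0
        assert het["se"] > hom["se"]
        assert het["Q_p"] < 0.01

    def test_q_matches_definition(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.3, 0.2, size=5)
        v = rng.uniform(0.02, 0.1, size=5)
        res = pn.random_effects_meta(d, v)
        w = 1 / v
        d_fe = np.sum(w * d) / np.sum(w)
        assert res["Q"] == pytest.approx(np.sum(w * (d - d_fe) ** 2), rel=1e-12)
        assert res["Q_df"] == 4

    def test_single_study_rejected(self):
        with pytest.raises(ValueError):
            pn.random_effects_meta(np.array([0.5]), np.array([0.1]))


class TestMetaAnalyze:
    def _three_cohorts(self, effect, seeds=(10, 11, 12)):
        results = []
        for i, s in enumerate(seeds):
            X, traits = make_cohort(s, n_case=100, n_control=100, n_features=30,
                                    effect=effect[i], cohort=f"c{i}")
            results.append(pn.differential_expression(X, traits))
        return results

    def test_matches_scalar_reference_functions(self):
        effect = [np.zeros(30)] * 3
        results = self._three_cohorts(effect)
        meta = pn.meta_analyze(results)
        ns = np.array([r.n for r in results], dtype=float)
        for f in ["F000", "F013", "F029"]:
            p = np.array([r.table.loc[f, "p"] for r in results])
            sign = np.sign([r.table.loc[f, "coef"] for r in results])
            z_ref, p_ref = pn.stouffer_combine(p, sign, ns)
            assert meta.table.loc[f, "stouffer_z"] == pytest.approx(z_ref, abs=1e-10)
            assert meta.table.loc[f, "stouffer_p"] == pytest.approx(p_ref, rel=1e-10)
            d = np.array([r.table.loc[f, "d"] for r in results])
            v = np.array([r.table.loc[f, "d_var"] for r in results])
            rem_ref = pn.random_effects_meta(d, v)
            assert meta.table.loc[f, "rem_d"] == pytest.approx(rem_ref["d"], abs=1e-10)
            assert meta.table.loc[f, "rem_p"] == pytest.approx(rem_ref["p"], rel=1e-8)
            assert meta.table.loc[f, "tau2"] == pytest.approx(rem_ref["tau2"], abs=1e-10)

    def test_consistent_effect_amplified_inconsistent_attenuated(self):
        base = np.zeros(30)
        base[0] = 0.6  # consistent everywhere
        flipped = base.copy()
        flipped[0] = -0.6
        results = self._three_cohorts([base, base, base])
        meta_con = pn.meta_analyze(results)
        results2 = self._three_cohorts([base, base, flipped])
        meta_inc = pn.meta_analyze(results2)
        assert abs(meta_con.table.loc["F000", "stouffer_z"]) > abs(
            meta_inc.table.loc["F000", "stouffer_z"]
        )
        assert meta_con.table.loc["F000", "direction_consistent"]
        assert not meta_inc.table.loc["F000", "direction_consistent"]
        # heterogeneity detected for the flipped feature
        assert meta_inc.table.loc["F000", "Q_p"] < 0.05

    def test_direction_consistency_thresholds(self):
        base = np.zeros(30)
        base[0] = 0.6
        results = self._three_cohorts([base, base, base])
        strict = direction_consistency(results, p_threshold=1e-30)
        assert not strict["F000"]
        loose = direction_consistency(results, p_threshold=0.1)
        assert loose["F000"]

    def test_mismatched_universe_rejected(self):
        results = self._three_cohorts([np.zeros(30)] * 3)
        results[1].table.index = [f"X{i}" for i in range(30)]
        with pytest.raises(ValueError, match="universe"):
            pn.meta_analyze(results)


class TestPersistentSet:
    def _setup(self, effect_value=1.0):
        effect = np.zeros(30)
        effect[:5] = effect_value
        results = []
        for i, s in enumerate((20, 21, 22)):
            X, traits = make_cohort(s, n_case=100, n_control=100, n_features=30,
                                    effect=effect, cohort=f"c{i}")
            results.append(pn.differential_expression(X, traits))
        meta = pn.meta_analyze(results)
        return results, meta

    def test_planted_features_pass_all_routes(self):
        results, meta = self._setup()
        universe = set(results[0].table.index)
        ps = pn.persistent_feature_set(universe, results[0], meta)
        assert set(ps.features) == {f"F{i:03d}" for i in range(5)}
        sub = ps.table.loc[ps.features]
        assert sub[["module_route", "training_route", "meta_route", "direction_route"]].all().all()

    def test_module_route_restricts(self):
        results, meta = self._setup()
        ps = pn.persistent_feature_set({"F000", "F001"}, results[0], meta)
        assert set(ps.features) == {"F000", "F001"}

    def test_disable_module_route(self):
        results, meta = self._setup()
        ps = pn.persistent_feature_set(set(), results[0], meta, use_module_route=False)
        assert set(ps.features) == {f"F{i:03d}" for i in range(5)}
        assert "module_route" not in ps.table.columns
        assert not ps.rule.startswith("module")

    def test_and_rule_is_subset_of_or_rule(self):
        results, meta = self._setup(effect_value=0.35)
        universe = set(results[0].table.index)
        ps_or = pn.persistent_feature_set(universe, results[0], meta, meta_rule="or")
        ps_and = pn.persistent_feature_set(universe, results[0], meta, meta_rule="and")
        assert set(ps_and.features) <= set(ps_or.features)

    def test_null_data_yields_empty_set(self):
        results, meta = self._setup(effect_value=0.0)
        universe = set(results[0].table.index)
        ps = pn.persistent_feature_set(universe, results[0], meta)
        assert ps.features == []

    def test_unknown_module_feature_rejected(self):
        results, meta = self._setup()
        with pytest.raises(ValueError, match="outside the universe"):
            pn.persistent_feature_set({"NOPE"}, results[0], meta)
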