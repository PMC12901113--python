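"""Feature selection and OLS fitting: importances, elbow, VIF, recovery."""

import numpy as np
import pandas as pd
import pytest

from typability import (
    ImportanceTable,
    TrainConfig,
    best_variant_per_attribute,
    fit_linear,
    inflection_count,
    make_feature_target_set,
    rf_importance,
    run_three_stage,
    validate,
    vif_filter,
)

FAST = TrainConfig(n_trees=100, n_permutation_repeats=3, seed=0)


@pytest.fixture(scope="module")
def informative_fixture():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(
        rng.standard_normal((500, 10)), columns=[f"v{i}" for i in range(10)]
    )
    y = X["v0"].values * 1.0 + rng.normal(0, 0.1, 500)
    return X, y


class TestRfImportance:
    def test_informative_variable_ranks_first(self, informative_fixture):
        X, y = informative_fixture
        table = rf_importance(X, y, FAST)
        assert table.ranked().index[0] == "v0"
        assert table.pct_inc_mse["v0"] > 10 * table.pct_inc_mse.drop("v0").max()

    def test_null_importances_near_zero(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.standard_normal((200, 5)), columns=list("abcde"))
        y = rng.standard_normal(200)
        table = rf_importance(X, y, FAST)
        # no variable should look informative when the target is independent
        assert table.pct_inc_mse.abs().max() < 50  # % of an already-noise-level MSE

    def test_deterministic_given_seed(self, informative_fixture):
        X, y = informative_fixture
        a = rf_importance(X, y, FAST).pct_inc_mse
        b = rf_importance(X, y, FAST).pct_inc_mse
        pd.testing.assert_series_equal(a, b)

    def test_missing_values_rejected(self, informative_fixture):
        X, y = informative_fixture
        X = X.copy()
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rf_importance(X, y, FAST)

    def test_too_few_items_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).standard_normal((20, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match=">= 50"):
            rf_importance(X, X["a"].values, FAST)


class TestBestVariant:
    def test_max_rule_and_single_variant_kept(self):
        table = ImportanceTable(
            pd.Series({"lower_all": 3.0, "lower_ns": 5.0, "keystrokes": 0.1}), 100, 0
        )
        kept = best_variant_per_attribute(
            table, {"lower_all": "case", "lower_ns": "case", "keystrokes": "keystrokes"}
        )
        assert set(kept) == {"lower_ns", "keystrokes"}

    def test_unmapped_variable_rejected(self):
        table = ImportanceTable(pd.Series({"a": 1.0, "b": 2.0}), 100, 0)
        with pytest.raises(ValueError, match="b"):
            best_variant_per_attribute(table, {"a": "x"})

    def test_full_roster_collapses_30_to_17(self, layout, resources):
        """One variant survives per attribute: 30 candidates become 17."""
        from typability import VARIABLE_ATTRIBUTE, extract_features, features_to_frame, generate_text_items

        items = generate_text_items(80, seed=3)
        X = features_to_frame(extract_features(it, layout, resources) for it in items)
        X = X[[c for c in X.columns if c in VARIABLE_ATTRIBUTE]]
        assert X.shape[1] == 30
        rng = np.random.default_rng(3)
        y = rng.standard_normal(len(X))
        table = rf_importance(X, y, FAST)
        kept = best_variant_per_attribute(table, VARIABLE_ATTRIBUTE)
        assert len(kept) == 17


class TestInflectionCount:
    def test_largest_drop(self):
        table = ImportanceTable(pd.Series([10, 9, 8, 2, 1], index=list("abcde")), 100, 0)
        assert inflection_count(table) == 3

    def test_tie_breaks_to_smaller_count(self):
        table = ImportanceTable(pd.Series([10, 5, 4, 3], index=list("abcd")), 100, 0)
        assert inflection_count(table) == 1

    def test_flat_decay_warns(self):
        table = ImportanceTable(pd.Series([4, 3, 2, 1], index=list("abcd")), 100, 0)
        with pytest.warns(UserWarning, match="no clear inflection"):
            assert inflection_count(table) == 1

    def test_too_few_variables_rejected(self):
        table = ImportanceTable(pd.Series([5, 1], index=list("ab")), 100, 0)
        with pytest.raises(ValueError):
            inflection_count(table)


class TestVifFilter:
    def test_duplicated_column_removed_by_importance(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"a": rng.standard_normal(100)})
        X["a_copy"] = X["a"]
        X["b"] = rng.standard_normal(100)
        importances = ImportanceTable(pd.Series({"a": 5.0, "a_copy": 1.0, "b": 2.0}), 100, 0)
        removed, vifs = vif_filter(X, 10.0, importances)
        assert removed == ["a_copy"]
        assert vifs.max() <= 10.0

    def test_independent_columns_untouched(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((300, 4)), columns=list("abcd"))
        removed, vifs = vif_filter(X, 10.0)
        assert removed == []
        assert (vifs < 2).all()

    def test_constructed_dependency_flagged_singular(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.standard_normal((150, 2)), columns=["x1", "x2"])
        X["x3"] = X["x1"] + X["x2"]
        importances = ImportanceTable(pd.Series({"x1": 3.0, "x2": 2.0, "x3": 1.0}), 100, 0)
        from typability import SelectionReport

        report = SelectionReport()
        removed, _ = vif_filter(X, 10.0, importances, report)
        assert removed == ["x3"]
        assert "singular" in report.events[0]["reason"]


class TestFitLinear:
    def test_exact_linear_target(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.standard_normal((80, 3)), columns=list("abc"))
        y = 1.5 + X @ [2.0, -1.0, 0.5]
        fit = fit_linear(X, y.values)
        assert fit.adj_r2 == pytest.approx(1.0)
        assert fit.rmse == pytest.approx(0.0, abs=1e-10)
        assert fit.intercept == pytest.approx(1.5)

    def test_beta_identity(self):
        """Standardised beta equals B * SD(x) / SD(y) on every fit."""
        X, y, _ = make_feature_target_set(300, noise_sd=0.3, seed=6)
        fit = fit_linear(X, y)
        sd_y = np.std(y, ddof=1)
        for name in fit.predictors:
            expected = fit.B[name] * X[name].std(ddof=1) / sd_y
            assert fit.beta[name] == pytest.approx(expected, rel=1e-8)

    def test_aic_prefers_informative_model(self):
        import statsmodels.api as sm

        X, y, _ = make_feature_target_set(400, noise_sd=0.2, seed=7)
        full = fit_linear(X, y)
        intercept_only_aic = sm.OLS(y, np.ones((len(y), 1))).fit().aic
        assert full.aic < intercept_only_aic

    def test_rank_deficient_rejected(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame({"a": rng.standard_normal(50)})
        X["b"] = 2 * X["a"]
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_linear(X, X["a"].values)


class TestCoefficientRecovery:
    def test_noiseless_recovery_exact(self):
        X, y, truth = make_feature_target_set(1000, noise_sd=0.0, seed=9)
        fit = fit_linear(X, y)
        for name, value in truth.coefficients.items():
            assert fit.B[name] == pytest.approx(value, abs=1e-8)
        assert fit.intercept == pytest.approx(truth.intercept, abs=1e-8)

    def test_noisy_recovery_within_3_se(self):
        X, y, truth = make_feature_target_set(1000, noise_sd=0.1, seed=10)
        fit = fit_linear(X, y)
        for name, value in truth.coefficients.items():
            assert abs(fit.B[name] - value) < 3 * fit.SE[name], name


class TestValidate:
    def test_in_sample_identity(self):
        X, y, _ = make_feature_target_set(300, noise_sd=0.3, seed=11)
        fit = fit_linear(X, y)
        from typability import LinearIndexModel

        model = LinearIndexModel("m", fit.intercept, dict(fit.B))
        result = validate(model, X, y)
        assert result.r2 == pytest.approx(fit.r2)
        assert result.rmse == pytest.approx(fit.rmse)

    def test_constant_shift_detected(self):
        X, y, truth = make_feature_target_set(200, noise_sd=0.0, seed=12)
        shifted = y + 0.37
        result = validate(truth, X, shifted)
        assert result.slope == pytest.approx(1.0)
        assert result.intercept == pytest.approx(0.37)
        assert result.r2 == pytest.approx(1.0)

    def test_missing_feature_rejected(self):
        X, y, truth = make_feature_target_set(200, seed=13)
        with pytest.raises(KeyError):
            validate(truth, X.drop(columns=[X.columns[0]]), y)


class TestThreeStage:
    def test_all_noise_keeps_at_most_a_spurious_predictor(self):
        """With a pure-noise target, stepwise pruning leaves nothing or a
        lone chance survivor (no multiplicity control is applied)."""
        rng = np.random.default_rng(14)
        X = pd.DataFrame(rng.standard_normal((200, 6)), columns=[f"n{i}" for i in range(6)])
        y = rng.standard_normal(200)
        model, _ = run_three_stage(X, y, {c: c for c in X.columns}, FAST)
        assert len(model.coefficients) <= 1

    def test_all_noise_intercept_only_warns(self):
        rng = np.random.default_rng(14)
        X = pd.DataFrame(rng.standard_normal((200, 6)), columns=[f"n{i}" for i in range(6)])
        y = rng.standard_normal(200)
        strict = TrainConfig(n_trees=100, n_permutation_repeats=3, seed=0, alpha=0.01)
        with pytest.warns(UserWarning, match="intercept-only"):
            model, _ = run_three_stage(X, y, {c: c for c in X.columns}, strict)
        assert model.coefficients == {}
        assert model.intercept == pytest.approx(y.mean())

    def test_recovery_and_determinism_small(self):
        from typability import make_selection_fixture

        X, y, informative, amap = make_selection_fixture(n=300, n_informative=4, n_noise=6, seed=15)
        model1, report1 = run_three_stage(X, y, amap, FAST)
        model2, report2 = run_three_stage(X, y, amap, FAST)
        assert model1.coefficients == model2.coefficients
        assert report1.to_frame().equals(report2.to_frame())
        selected = set(model1.coefficients)
        assert selected <= set(informative) | set()  # no noise variable survives
        assert len(selected & set(informative)) >= 3
        assert (model1 and max(
            fit_linear(X[list(selected)], y).p
        ) < 0.05)
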