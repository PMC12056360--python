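"""Normality gate, Box-Cox, CV elastic net, and stability selection."""

import numpy as np
import pytest

import strokeconn as sc
from strokeconn.stability import (
    StabilityElasticNet,
    _candidate_grid,
    fit_elastic_net_cv,
    normality_gate,
    rank_coefficients,
    stability_selection,
)


class TestShapiroWilk:
    def test_normal_sample_usually_passes(self):
        passes = 0
        for seed in range(40):
            x = np.random.default_rng(seed).standard_normal(200)
            _, p = sc.shapiro_wilk(x)
            passes += p > 0.05
        assert passes >= 33  # ~95% expected

    def test_lognormal_sample_rejected(self):
        for seed in range(10):
            x = np.exp(np.random.default_rng(100 + seed).standard_normal(200))
            _, p = sc.shapiro_wilk(x)
            assert p < 0.05

    def test_tiny_or_constant_input_rejected(self):
        with pytest.raises(ValueError):
            sc.shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError, match="constant"):
            sc.shapiro_wilk(np.ones(20))


class TestBoxCox:
    def test_normal_data_lambda_near_one(self):
        rng = np.random.default_rng(0)
        y = rng.normal(10, 1, 500)
        _, lam, _ = sc.boxcox_transform(y)
        assert abs(lam - 1) < 0.5

    def test_lognormal_data_lambda_near_zero(self):
        rng = np.random.default_rng(1)
        y = np.exp(rng.standard_normal(500))
        yt, lam, shift = sc.boxcox_transform(y)
        assert abs(lam) < 0.3
        assert shift == 0.0

    def test_zero_lambda_branch_equals_log(self):
        from scipy.stats import boxcox as scipy_boxcox
        y = np.random.default_rng(2).uniform(0.5, 4.0, 100)
        np.testing.assert_allclose(scipy_boxcox(y, lmbda=0.0), np.log(y), atol=1e-12)

    def test_non_positive_data_shifted(self):
        y = np.random.default_rng(3).normal(0, 1, 200)
        yt, lam, shift = sc.boxcox_transform(y)
        assert shift > -y.min()
        assert np.all(np.isfinite(yt))


class TestNormalityGate:
    def test_normal_outcome_kept_raw(self):
        y = np.random.default_rng(4).standard_normal(200)
        yt, rec = normality_gate(y, "FM")
        assert not rec.transformed
        np.testing.assert_array_equal(yt, y)

    def test_skewed_outcome_transformed(self):
        y = np.exp(np.random.default_rng(5).standard_normal(200))
        yt, rec = normality_gate(y, "TUG")
        assert rec.transformed
        assert rec.shapiro_p < 0.05
        assert rec.boxcox_lambda is not None
        # the transform should look much more normal
        _, p_after = sc.shapiro_wilk(yt)
        assert p_after > rec.shapiro_p


class TestCandidateGrid:
    def test_hundred_candidates_within_stated_ranges(self):
        mixing, penalty = _candidate_grid()
        assert mixing.size * penalty.size == 100
        assert mixing.min() == pytest.approx(0.05) and mixing.max() == pytest.approx(1.0)
        assert penalty.min() == pytest.approx(0.0002) and penalty.max() == pytest.approx(0.36)


class TestElasticNetCV:
    def test_dominant_true_feature_has_largest_coefficient(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((100, 24))
        y = X[:, 0] * 1.0  # exact, no noise
        fit = fit_elastic_net_cv(X, y, seed=0)
        assert fit.beta[0] != 0
        assert np.all(np.abs(fit.beta[1:]) < abs(fit.beta[0]))

    def test_pure_noise_outcome_selects_few_features(self):
        counts = []
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            X = rng.standard_normal((60, 24))
            y = rng.standard_normal(60)
            fit = fit_elastic_net_cv(X, y, seed=seed)
            counts.append(int((fit.beta != 0).sum()))
        assert np.median(counts) <= 4

    def test_lasso_corner_splits_duplicated_features(self):
        """At the pure-L1 corner a duplicated column is not co-selected."""
        from strokeconn.stability import _candidate_grid
        from sklearn.linear_model import ElasticNet
        rng = np.random.default_rng(7)
        x = rng.standard_normal(80)
        X = np.column_stack([x, x, rng.standard_normal((80, 3))])
        y = x + rng.normal(0, 0.1, 80)
        model = ElasticNet(alpha=0.1, l1_ratio=1.0).fit(
            (X - X.mean(0)) / X.std(0), y - y.mean()
        )
        assert (np.abs(model.coef_[:2]) > 1e-10).sum() == 1

    def test_too_few_cases_rejected(self):
        X = np.zeros((5, 3))
        with pytest.raises(ValueError, match="complete cases"):
            fit_elastic_net_cv(X, np.zeros(5), seed=0)

    def test_small_n_reduces_folds_with_warning(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((11, 4))
        y = X[:, 0] + rng.normal(0, 0.2, 11)
        with pytest.warns(UserWarning, match="reducing CV folds"):
            fit_elastic_net_cv(X, y, seed=0, n_folds=8)


class TestRankCoefficients:
    def test_proportional_ranking(self):
        assert rank_coefficients({"a": 0.5, "b": 0.25}) == {"a": 100.0, "b": 50.0}

    def test_single_member_is_hundred(self):
        assert rank_coefficients({"a": -0.1}) == {"a": 100.0}

    def test_magnitude_rule_ignores_sign(self):
        ranks = rank_coefficients({"a": -0.4, "b": 0.2})
        assert ranks == {"a": 100.0, "b": 50.0}

    def test_empty_set_gives_empty_output(self):
        assert rank_coefficients({}) == {}


class TestStabilitySelection:
    def test_planted_features_enter_strong_set(self):
        X, y = sc.simulate_feature_outcome(
            37, 24, [(0, 0.8), (1, 0.8), (2, 0.8)], noise_sd=1.13, seed=12
        )
        res = stability_selection(X, y, repeats=20, base_seed=3)
        assert {"x0", "x1", "x2"} <= set(res.strong_set)
        assert max(res.rank_percent.values()) == pytest.approx(100.0)
        # direction of a positive planted effect is positive
        assert res.direction["x0"] == 1

    def test_deterministic_under_fixed_base_seed(self):
        X, y = sc.simulate_feature_outcome(37, 24, [(0, 1.0)], noise_sd=0.5, seed=13)
        r1 = stability_selection(X, y, repeats=5, base_seed=7)
        r2 = stability_selection(X, y, repeats=5, base_seed=7)
        np.testing.assert_array_equal(r1.selection_count, r2.selection_count)
        assert r1.strong_set == r2.strong_set
        np.testing.assert_array_equal(
            r1.per_repeat["cv_rmse"], r2.per_repeat["cv_rmse"]
        )

    def test_feature_rescaling_leaves_selection_unchanged(self):
        X, y = sc.simulate_feature_outcome(40, 10, [(2, 1.0)], noise_sd=0.5, seed=14)
        r1 = stability_selection(X, y, repeats=5, base_seed=1)
        X2 = X.copy()
        X2[:, 2] *= 1000.0
        X2[:, 5] /= 977.0
        r2 = stability_selection(X2, y, repeats=5, base_seed=1)
        np.testing.assert_array_equal(r1.selection_count, r2.selection_count)


class TestModelInterface:
    def test_incomplete_cases_dropped(self):
        X, y = sc.simulate_feature_outcome(30, 5, [(0, 1.0)], noise_sd=0.3, seed=15)
        y = y + 10  # keep positive for the gate
        y[3] = np.nan
        X[7, 2] = np.nan
        model = StabilityElasticNet(y, X, outcome="FM")
        assert model.X.shape[0] == 28

    def test_summary_reports_strong_set(self):
        import pandas as pd
        X, y = sc.simulate_feature_outcome(37, 8, [(0, 1.5)], noise_sd=0.3, seed=16)
        frame = pd.DataFrame(X, columns=[f"roi{i}" for i in range(8)])
        model = StabilityElasticNet.from_dataframe(frame, y, outcome="FM", metric="GE")
        res = model.fit(repeats=5, base_seed=0)
        assert "roi0" in res.strong_set
        out = res.to_frame()
        assert set(out.columns) == {"outcome", "metric", "roi", "rank_percent",
                                    "direction", "selection_count"}
        assert "Stability elastic net" in res.summary()
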