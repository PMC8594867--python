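import numpy as np
import pandas as pd
import pytest

from pcmbench.explanatory import (
    anova_strategy,
    classify_metric_sensitivity,
    expected_performance,
    fit_metric_model,
    fit_predicted_ratio_model,
    pearson_ci,
    rank_strategies,
    tukey_pairwise,
)
from pcmbench.strategies import StrategyName
from pcmbench.synthetic import PlantedEffects, simulate_predicted_ratios

STRATEGIES = [s.value for s in StrategyName]


def _ratio_observations(n, rng, effects=None, dispersion=1.5, strategy="no_resampling",
                        n_test=40, seed=0):
    cov = pd.DataFrame(
        {
            "r_training": rng.random(n),
            "r_test": rng.random(n),
            "n_int": rng.integers(5, 100, n).astype(float),
            "n_seq": rng.integers(200, 1200, n).astype(float),
            "k_fold": rng.integers(0, 5, n),
            "n_test": np.full(n, n_test),
        }
    )
    effects = effects or PlantedEffects(
        intercept=-0.4, r_training=1.2, r_test=0.9, n_int=0.004, n_seq=-0.0006,
        fold_offsets=(0.15, -0.1, 0.05, 0.0),
    )
    cov["r_pred"] = simulate_predicted_ratios(cov, effects, dispersion, seed=seed)
    cov["strategy"] = strategy
    cov["protein_id"] = [f"P{i}" for i in range(n)]
    return cov, effects


def _metric_observations(n_per_stratum, rng, strategy_effects, noise=0.1):
    rows = []
    for s in STRATEGIES:
        for i in range(n_per_stratum):
            n_int = float(rng.integers(5, 100))
            n_seq = float(rng.integers(200, 1200))
            k_fold = int(rng.integers(0, 5))
            y = (
                0.5
                + strategy_effects.get(s, 0.0)
                + 0.001 * n_int
                - 0.0001 * n_seq
                + 0.02 * k_fold
                + rng.normal(0, noise)
            )
            rows.append(
                {
                    "strategy": s,
                    "k_fold": k_fold,
                    "n_int": n_int,
                    "n_seq": n_seq,
                    "mcc": y,
                    "protein_id": f"P{i}",
                }
            )
    return pd.DataFrame(rows)


class TestPredictedRatioModel:
    def test_planted_coefficients_inside_confidence_intervals(self, rng):
        obs, effects = _ratio_observations(2000, rng, seed=3)
        fit = fit_predicted_ratio_model(obs, "no_resampling")
        ci = fit.conf_int()
        planted = {
            "Intercept": effects.intercept,
            "r_training": effects.r_training,
            "r_test": effects.r_test,
            "n_int": effects.n_int,
            "n_seq": effects.n_seq,
        }
        for name, value in planted.items():
            low, high = ci.loc[name]
            assert low <= value <= high, (name, value, low, high)
        assert fit.dispersion > 1.0  # overdispersion picked up

    def test_constant_ratio_gives_null_slopes(self, rng):
        obs, _ = _ratio_observations(500, rng)
        obs["r_pred"] = 0.5
        fit = fit_predicted_ratio_model(obs, "no_resampling")
        for name in ("r_training", "r_test", "n_int", "n_seq"):
            assert abs(fit.params[name]) < 1e-6

    def test_enforced_strategy_rejected(self, rng):
        obs, _ = _ratio_observations(50, rng, strategy="resampling_after_clustering")
        with pytest.raises(ValueError, match="enforced"):
            fit_predicted_ratio_model(obs, "resampling_after_clustering")

    def test_missing_strategy_rejected(self, rng):
        obs, _ = _ratio_observations(50, rng)
        with pytest.raises(ValueError):
            fit_predicted_ratio_model(obs, "semi_resampling")

    def test_quasibinomial_point_estimates_equal_binomial(self, rng):
        """Free dispersion rescales the standard errors only."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        obs, _ = _ratio_observations(400, rng, seed=9)
        fit = fit_predicted_ratio_model(obs, "no_resampling")
        plain = smf.glm(
            fit.formula,
            data=obs,
            family=sm.families.Binomial(),
            var_weights=np.asarray(obs["n_test"], float),
        ).fit()
        assert np.allclose(fit.params, plain.params, atol=1e-8)
        assert not np.allclose(fit.bse, plain.bse)


class TestMetricModel:
    def test_planted_strategy_effect_recovered(self, rng):
        effects = {"semi_resampling": 0.1}
        obs = _metric_observations(300, rng, effects)
        fit = fit_metric_model(obs, "mcc")
        name = [n for n in fit.params.index if "semi_resampling" in n][0]
        low, high = fit.conf_int().loc[name]
        assert low <= 0.1 <= high
        assert fit.params[name] == pytest.approx(0.1, abs=0.05)

    def test_all_zero_adjusted_response_gives_zero_coefficients(self, rng):
        obs = _metric_observations(50, rng, {}, noise=0.0)
        obs["adjusted_self"] = 0.0
        fit = fit_metric_model(obs, "adjusted_self")
        assert np.allclose(fit.params, 0.0, atol=1e-10)

    def test_all_undefined_response_rejected(self, rng):
        obs = _metric_observations(20, rng, {})
        obs["mcc"] = np.nan
        with pytest.raises(ValueError):
            fit_metric_model(obs, "mcc")

    def test_unknown_response_rejected(self, rng):
        obs = _metric_observations(20, rng, {})
        with pytest.raises(ValueError):
            fit_metric_model(obs, "f2_score")

    def test_single_strategy_rejected(self, rng):
        obs = _metric_observations(20, rng, {})
        obs = obs[obs["strategy"] == "no_resampling"]
        with pytest.raises(ValueError):
            fit_metric_model(obs, "mcc")


class TestAnovaAndSensitivity:
    def test_strong_effect_detected(self, rng):
        obs = _metric_observations(200, rng, {"semi_resampling": 0.3})
        fit = fit_metric_model(obs, "mcc")
        assert anova_strategy(fit) < 1e-3

    def test_null_effect_usually_not_detected(self, rng):
        ps = []
        for rep in range(20):
            obs = _metric_observations(60, rng, {})
            ps.append(anova_strategy(fit_metric_model(obs, "mcc")))
        # under the null the p-values are roughly uniform
        assert np.mean(np.array(ps) < 0.05) < 0.3
        assert min(ps) > 1e-6

    def test_missing_strategy_term_rejected(self, rng):
        obs, _ = _ratio_observations(200, rng)
        fit = fit_predicted_ratio_model(obs, "no_resampling")
        with pytest.raises(ValueError):
            anova_strategy(fit)

    def test_classification_follows_alpha(self, rng):
        sensitive = fit_metric_model(
            _metric_observations(200, rng, {"semi_resampling": 0.3}), "mcc"
        )
        insensitive = fit_metric_model(_metric_observations(200, rng, {}), "mcc")
        result = classify_metric_sensitivity({"a": sensitive, "b": insensitive})
        assert result["a"] == "imbalance_sensitive"
        assert result["b"] == "imbalance_insensitive"


class TestTukey:
    def test_six_contrasts_and_adjustment_dominates_raw(self, rng):
        obs = _metric_observations(100, rng, {"semi_resampling": 0.05})
        table = tukey_pairwise(fit_metric_model(obs, "mcc"))
        assert len(table) == 6
        assert (table["p_tukey"] >= table["p_raw"] - 1e-12).all()

    def test_planted_ordering_recovered(self, rng):
        effects = {
            "no_resampling": 0.0,
            "resampling_after_clustering": 0.2,
            "resampling_before_clustering": 0.4,
            "semi_resampling": 0.6,
        }
        obs = _metric_observations(250, rng, effects, noise=0.05)
        table = tukey_pairwise(fit_metric_model(obs, "mcc"))
        assert (table["p_tukey"] < 0.01).all()
        for _, row in table.iterrows():
            a, b = row["contrast"].split(" - ")
            assert np.sign(row["estimate"]) == np.sign(effects[a] - effects[b])


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        out = pearson_ci(x, x)
        assert out["r"] == pytest.approx(1.0)

    def test_matches_fisher_z_formula_on_fixture(self):
        x = np.array([1.2, 3.4, 2.2, 5.1, 4.4, 0.7, 2.9, 3.3, 4.8, 1.9])
        y = np.array([0.9, 2.8, 2.5, 4.2, 4.9, 1.1, 2.2, 3.9, 4.1, 2.4])
        out = pearson_ci(x, y)
        r = np.corrcoef(x, y)[0, 1]
        z = np.arctanh(r)
        se = 1 / np.sqrt(len(x) - 3)
        assert out["r"] == pytest.approx(r)
        assert out["ci_low"] == pytest.approx(np.tanh(z - 1.959963984540054 * se), abs=1e-9)
        assert out["ci_high"] == pytest.approx(np.tanh(z + 1.959963984540054 * se), abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_ci([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            pearson_ci([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRanking:
    def test_dominant_strategy_ranks_first(self, rng):
        effects = {"semi_resampling": 0.5}
        fits = {
            m: fit_metric_model(_metric_observations(150, rng, effects), "mcc")
            for m in ("mcc", "auroc")
        }
        ranking = rank_strategies(fits)
        top = ranking[ranking["rank"] == 1]
        assert set(top["strategy"]) == {"semi_resampling"}

    def test_ranking_invariant_to_affine_response_rescale(self, rng):
        obs = _metric_observations(150, rng, {"semi_resampling": 0.2,
                                              "resampling_before_clustering": -0.1})
        obs2 = obs.copy()
        obs2["mcc"] = 10 * obs2["mcc"] + 3
        r1 = rank_strategies({"m": fit_metric_model(obs, "mcc")})
        r2 = rank_strategies({"m": fit_metric_model(obs2, "mcc")})
        assert list(r1["strategy"]) == list(r2["strategy"])

    def test_expected_performance_matches_cell_means_structure(self, rng):
        obs = _metric_observations(400, rng, {"semi_resampling": 0.25}, noise=0.02)
        fit = fit_metric_model(obs, "mcc")
        expect = expected_performance(fit)
        diff = expect["semi_resampling"] - expect["no_resampling"]
        assert diff == pytest.approx(0.25, abs=0.02)
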