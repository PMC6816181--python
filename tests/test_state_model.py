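"""Multinomial logit engine, AIC selection, odds ratios, nonparametric tests."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as smapi
from scipy import stats

from stormbird.state_model import (MNLFit, SeparationError, aic_select, fit_mnl,
                                   kruskal_wallis, model_set, odds_ratio,
                                   state_probability, wilcoxon_ranksum,
                                   coefficient_table)
from stormbird.synthetic import simulate_regression_data


class TestFitMnl:
    def test_null_model_closed_form(self):
        y = np.array([1] * 600 + [0] * 400)
        fit = fit_mnl(y, None, model="null")
        assert np.isclose(float(fit.coef.iloc[0, 0]), math.log(600 / 400), atol=1e-8)
        assert np.isclose(fit.llf, 600 * math.log(0.6) + 400 * math.log(0.4), atol=1e-8)
        assert np.isclose(fit.aic, 2 * 1 - 2 * fit.llf)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_irls_oracle(self, seed):
        d = simulate_regression_data(500, seed=seed)
        fit = fit_mnl(d["state2"].to_numpy(), d[["bp_kpa", "wv_kmh"]],
                      standardize=False)
        X = smapi.add_constant(d[["bp_kpa", "wv_kmh"]].to_numpy())
        oracle = smapi.Logit(d["state2"], X).fit(disp=0)
        assert np.allclose(fit.coef.iloc[:, 0], oracle.params, atol=1e-6)
        assert np.allclose(fit.se.iloc[:, 0], oracle.bse, atol=1e-6)
        assert np.isclose(fit.llf, oracle.llf, atol=1e-6)

    def test_score_vanishes_at_optimum(self):
        d = simulate_regression_data(800, seed=42)
        fit = fit_mnl(d["state2"].to_numpy(), d[["bp_kpa", "wv_kmh"]])
        s = fit.estimator.score_vector(d[["bp_kpa", "wv_kmh"]].to_numpy(),
                                       d["state2"].to_numpy())
        assert np.abs(s).max() < 1e-6

    def test_standardization_changes_scale_not_fit(self):
        d = simulate_regression_data(600, seed=3)
        d["bp_kpa"] = 101.3 + 0.4 * d["bp_kpa"]      # put covariates on raw scale
        d["wv_kmh"] = 10 + 8 * d["wv_kmh"]
        raw = fit_mnl(d["state2"].to_numpy(), d[["bp_kpa", "wv_kmh"]],
                      standardize=False)
        std = fit_mnl(d["state2"].to_numpy(), d[["bp_kpa", "wv_kmh"]],
                      standardize=True)
        assert np.isclose(raw.llf, std.llf, atol=1e-8)
        assert np.isclose(raw.aic, std.aic, atol=1e-8)
        for cov in ("bp_kpa", "wv_kmh"):
            sd = std.scale_[cov][1]
            assert np.isclose(float(std.coef.loc[cov].iloc[0]),
                              float(raw.coef.loc[cov].iloc[0]) * sd, rtol=1e-6)
        Xp = d[["bp_kpa", "wv_kmh"]].to_numpy()
        assert np.allclose(raw.estimator.predict_proba(Xp),
                           std.estimator.predict_proba(Xp), atol=1e-8)

    def test_three_state_reduces_consistently(self):
        # K=3 multinomial logit against statsmodels MNLogit
        rng = np.random.default_rng(9)
        X = rng.standard_normal((600, 2))
        eta1 = 0.3 + 0.5 * X[:, 0]
        eta2 = -0.2 + 0.8 * X[:, 1]
        p = np.column_stack([np.ones(600), np.exp(eta1), np.exp(eta2)])
        p /= p.sum(axis=1, keepdims=True)
        y = np.array([rng.choice(3, p=pi) for pi in p])
        fit = fit_mnl(y, pd.DataFrame(X, columns=["a", "b"]), standardize=False)
        oracle = smapi.MNLogit(y, smapi.add_constant(X)).fit(disp=0)
        assert np.allclose(fit.coef.to_numpy(), oracle.params, atol=1e-5)
        assert np.isclose(fit.llf, oracle.llf, atol=1e-6)

    def test_separation_detected(self):
        x = np.linspace(-2, 2, 200)
        y = (x > 0).astype(int)
        with pytest.raises(SeparationError):
            fit_mnl(y, pd.DataFrame({"x": x}), standardize=False)

    def test_rank_deficiency_names_columns(self):
        d = simulate_regression_data(200, seed=1)
        d["dup"] = d["bp_kpa"] * 2.0
        with pytest.raises(ValueError, match="collinear"):
            fit_mnl(d["state2"].to_numpy(), d[["bp_kpa", "dup"]], standardize=False)

    def test_constant_covariate_rejected(self):
        d = simulate_regression_data(100, seed=2)
        d["const"] = 5.0
        with pytest.raises(ValueError, match="constant"):
            fit_mnl(d["state2"].to_numpy(), d[["const"]], standardize=True)

    def test_type_one_error_calibration(self):
        # planted null effects: |t| > 1.96 should fire at ~5 %
        rng = np.random.default_rng(77)
        hits = 0
        reps = 400
        for _ in range(reps):
            x = rng.standard_normal(250)
            y = (rng.uniform(size=250) < 0.6).astype(int)
            fit = fit_mnl(y, pd.DataFrame({"x": x}), standardize=False)
            if abs(float(fit.tvalue.loc["x"].iloc[0])) > 1.96:
                hits += 1
        assert 0.02 <= hits / reps <= 0.09


class TestAicSelect:
    def _fit(self, llf, k, n=1000):
        empty = pd.DataFrame()
        return MNLFit(model=f"m{k}", covariates=[], coef=empty, se=empty,
                      tvalue=empty, llf=llf, aic=2 * k - 2 * llf, n=n, k=k,
                      converged=True, standardized=False)

    def test_formula_and_delta(self):
        out = aic_select({"a": self._fit(-100, 3), "b": self._fit(-105, 2)})
        assert out["AIC"].tolist() == [206.0, 214.0]
        assert out["dAIC"].tolist() == [0.0, 8.0]
        assert out["co_best"].tolist() == [True, False]

    def test_identical_models_tie(self):
        out = aic_select({"a": self._fit(-100, 2), "b": self._fit(-100, 2)})
        assert out["co_best"].all()

    def test_mixed_n_rejected(self):
        with pytest.raises(ValueError, match="not comparable"):
            aic_select({"a": self._fit(-100, 2, n=500), "b": self._fit(-90, 2, n=600)})

    def test_null_wins_on_null_data(self):
        # With no true effects, AIC admits a spurious covariate with
        # probability P(chi2_1 > 2) ~ 0.157 per model, so the null is
        # strictly best in ~72 % of replicates and co-best in ~91 %.
        rng = np.random.default_rng(123)
        wins = cobest = 0
        reps = 200
        for i in range(reps):
            d = simulate_regression_data(300, beta=(0.4, 0.0, 0.0),
                                         seed=int(rng.integers(2 ** 31)))
            rank = aic_select(model_set(d))
            if rank["model"].iloc[0] == "null":
                wins += 1
            if bool(rank.loc[rank["model"] == "null", "co_best"].iloc[0]):
                cobest += 1
        assert wins / reps >= 0.6
        assert cobest / reps >= 0.8


class TestOddsAndProbability:
    # printed coefficient table of the three-event study, used as inputs
    @pytest.mark.parametrize("beta,direction,expected", [
        (0.0978, "per-unit-decrease", 0.91),
        (-0.1744, "per-unit-increase", 0.84),
        (0.2600, "per-unit-decrease", 0.77),
        (0.1822, "per-unit-increase", 1.20),
        (-0.1088, "per-unit-increase", 0.90),
    ])
    def test_reported_odds_ratios(self, beta, direction, expected):
        coef = pd.DataFrame({"active": [0.5, beta]}, index=["Intercept", "x"])
        fit = MNLFit(model="m", covariates=["x"], coef=coef, se=coef * 0 + 1,
                     tvalue=coef, llf=0.0, aic=0.0, n=1, k=2, converged=True,
                     standardized=True)
        assert round(odds_ratio(fit, "x", direction), 2) == expected

    def test_odds_directions_multiply_to_one(self):
        coef = pd.DataFrame({"active": [0.1, -0.37]}, index=["Intercept", "x"])
        fit = MNLFit(model="m", covariates=["x"], coef=coef, se=coef * 0 + 1,
                     tvalue=coef, llf=0.0, aic=0.0, n=1, k=2, converged=True,
                     standardized=True)
        assert np.isclose(odds_ratio(fit, "x", "per-unit-increase")
                          * odds_ratio(fit, "x", "per-unit-decrease"), 1.0)

    def test_state_probability_at_intercept(self):
        coef = pd.DataFrame({"active": [0.9991]}, index=["Intercept"])
        fit = MNLFit(model="null", covariates=[], coef=coef, se=coef * 0 + 1,
                     tvalue=coef, llf=0.0, aic=0.0, n=1, k=1, converged=True,
                     standardized=False)
        assert np.isclose(state_probability(fit), 0.7309, atol=1e-4)
        zero = coef * 0.0
        fit0 = MNLFit(model="null", covariates=[], coef=zero, se=zero + 1,
                      tvalue=zero, llf=0.0, aic=0.0, n=1, k=1, converged=True,
                      standardized=False)
        assert state_probability(fit0) == 0.5

    def test_probability_monotone_in_covariate(self):
        d = simulate_regression_data(2000, beta=(0.5, 0.0, -0.4), seed=8)
        fit = fit_mnl(d["state2"].to_numpy(), d[["wv_kmh"]], standardize=False)
        grid = [state_probability(fit, {"wv_kmh": v}) for v in np.linspace(-2, 2, 9)]
        assert all(a > b for a, b in zip(grid, grid[1:]))
        assert all(0 < p < 1 for p in grid)


class TestKruskalWallis:
    def test_identical_groups_high_p(self):
        res = kruskal_wallis([1, 2, 3], [1, 2, 3])
        assert res.p_value > 0.9

    def test_hand_computed_h(self):
        res = kruskal_wallis([1, 2, 3], [4, 5, 6], method="asymptotic")
        assert np.isclose(res.statistic, 3.857142857, atol=1e-6)

    def test_degenerate_all_equal(self):
        res = kruskal_wallis([5, 5], [5, 5, 5])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(31)
        a, b = rng.normal(size=3), rng.normal(size=3)
        res = kruskal_wallis(a, b, method="exact")
        # independent oracle: scipy H over all itertools splits
        import itertools
        pooled = np.concatenate([a, b])
        h_obs = stats.kruskal(a, b).statistic
        count = total = 0
        for combo in itertools.combinations(range(6), 3):
            g1 = pooled[list(combo)]
            g2 = pooled[[i for i in range(6) if i not in combo]]
            total += 1
            if stats.kruskal(g1, g2).statistic >= h_obs - 1e-12:
                count += 1
        assert np.isclose(res.p_value, count / total, atol=1e-12)

    def test_statistic_matches_scipy(self):
        rng = np.random.default_rng(32)
        groups = [rng.normal(size=20), rng.normal(0.5, 1, size=25),
                  rng.normal(size=15)]
        res = kruskal_wallis(*groups)
        h, p = stats.kruskal(*groups)
        assert np.isclose(res.statistic, h) and np.isclose(res.p_value, p)


class TestWilcoxonRankSum:
    def test_same_multiset_zero_z(self):
        res = wilcoxon_ranksum([1, 2, 3, 4], [1, 2, 3, 4], method="asymptotic")
        assert abs(res.z) < 1e-12

    def test_hand_computed_extreme(self):
        res = wilcoxon_ranksum([1, 2], [3, 4, 5], method="asymptotic")
        # W = 3, mu = 6, var = 2*3*6/12 = 3
        assert res.statistic == 3.0
        assert np.isclose(res.z, (3 - 6) / math.sqrt(3))

    def test_exact_p_matches_scipy_exact(self):
        rng = np.random.default_rng(33)
        for n1, n2 in [(4, 5), (6, 6), (8, 8)]:
            a, b = rng.normal(size=n1), rng.normal(0.8, 1, size=n2)
            res = wilcoxon_ranksum(a, b, method="exact")
            _, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert np.isclose(res.p_value, p, atol=1e-9)

    def test_tie_corrected_z(self):
        a = [1, 1, 2, 2, 3]
        b = [2, 3, 3, 4, 4]
        res = wilcoxon_ranksum(a, b, method="asymptotic")
        assert res.tie_corrected
        # oracle: tie-corrected normal approximation from first principles
        ranks = stats.rankdata(np.concatenate([a, b]))
        w = ranks[:5].sum()
        ties = np.array([2, 3, 3, 2])
        var = 5 * 5 / 12 * (11 - (ties ** 3 - ties).sum() / (10 * 9))
        assert np.isclose(res.z, (w - 27.5) / math.sqrt(var))


def test_coefficient_table_schema():
    d = simulate_regression_data(500, seed=4)
    fits = model_set(d)
    table = coefficient_table({"EventA": fits["global"]})
    assert list(table.columns) == ["event", "variable", "coefficient",
                                   "std_error", "t_value", "signif"]
    assert table["variable"].tolist() == ["Intercept", "Barometric Pressure",
                                          "Wind Speed"]
    assert set(table["signif"]) <= {"", "*", "**"}
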