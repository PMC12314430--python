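import numpy as np
import pandas as pd
import pytest

from risesync import regression as reg
from risesync.synth import synth_feature_table


class TestPrepareResponses:
    def test_natural_log_scale(self):
        table = pd.DataFrame(
            {
                "rise_time_ms": np.full(20, np.e**3.0),
                "median_abs_ms": np.linspace(10, 60, 20),
                "median_signed_ms": np.linspace(-30, 30, 20),
            }
        )
        out, checks = reg.prepare_responses(table)
        assert np.allclose(out["log_rise_time_ms"], 3.0)
        assert "log_median_abs_ms" in out
        assert not checks["median_signed_ms"].transformed

    def test_nonpositive_raises_with_rows(self):
        table = pd.DataFrame(
            {"rise_time_ms": [10.0, -1.0, 5.0], "median_signed_ms": [0.0, 1.0, 2.0]}
        )
        with pytest.raises(ValueError, match=r"\[1\]"):
            reg.prepare_responses(table, log_columns=["rise_time_ms"])

    def test_normal_sample_w_near_one(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"median_signed_ms": rng.normal(0, 10, 400)})
        _, checks = reg.prepare_responses(table, log_columns=[])
        check = checks["median_signed_ms"]
        assert check.w > 0.99
        assert check.p > 0.05


class TestFitLm:
    def test_exact_line(self):
        table = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0], "y": [1.0, 3.0, 5.0, 7.0]})
        fit = reg.fit_lm(table, "y", ["x"], categorical={})
        by_name = {s.name: s for s in fit.stats}
        assert by_name["Intercept"].b == pytest.approx(1.0)
        assert by_name["x"].b == pytest.approx(2.0)
        assert fit.rsquared == pytest.approx(1.0)
        assert by_name["x"].se == pytest.approx(0.0, abs=1e-10)

    def test_matches_hand_linear_algebra(self):
        # closed form (X'X)^-1 X'y on a 5-row example
        x1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        x2 = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        y = np.array([3.1, 4.2, 8.3, 9.1, 12.0])
        X = np.column_stack([np.ones(5), x1, x2])
        beta_hat = np.linalg.solve(X.T @ X, X.T @ y)
        table = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
        fit = reg.fit_lm(table, "y", ["x1", "x2"], categorical={})
        got = [s.b for s in fit.stats]
        assert got == pytest.approx(beta_hat.tolist())

    def test_categorical_reference_coding(self):
        table = pd.DataFrame(
            {
                "weight": pd.Categorical(
                    ["weak", "strong", "weak", "strong", "weak", "strong"],
                    categories=["weak", "strong"],
                ),
                "y": [1.0, 2.1, 0.9, 2.0, 1.1, 1.9],
            }
        )
        fit = reg.fit_lm(table, "y", ["weight"])
        names = [s.name for s in fit.stats]
        assert names == ["Intercept", "weight[strong]"]
        by_name = {s.name: s for s in fit.stats}
        assert by_name["Intercept"].b == pytest.approx(1.0)
        assert by_name["weight[strong]"].b == pytest.approx(1.0)

    def test_rank_deficiency_names_columns(self):
        table = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0], "y": [1, 2, 3, 4]}
        )
        with pytest.raises(ValueError, match="a~b"):
            reg.fit_lm(table, "y", ["a", "b"], categorical={})

    def test_ci_consistent_with_se(self):
        table = synth_feature_table(
            100, {"sonority": 0.5, "serial_order": -0.2}, noise_sd=1.0, seed=3
        )
        fit = reg.fit_lm(table, "y", ["sonority", "serial_order"], categorical={})
        import scipy.stats

        tcrit = scipy.stats.t.ppf(0.975, fit.df_resid)
        for s in fit.stats:
            assert s.ci_low == pytest.approx(s.b - tcrit * s.se, rel=1e-9)
            assert s.ci_high == pytest.approx(s.b + tcrit * s.se, rel=1e-9)

    def test_beta_std_scale_invariant(self):
        table = synth_feature_table(
            150, {"sonority": 0.5, "nucleus_dur_s": 2.0}, noise_sd=0.5, seed=1
        )
        fit1 = reg.fit_lm(table, "y", ["sonority", "nucleus_dur_s"], categorical={})
        table2 = table.copy()
        table2["nucleus_dur_s"] = table2["nucleus_dur_s"] * 1000.0
        fit2 = reg.fit_lm(table2, "y", ["sonority", "nucleus_dur_s"], categorical={})
        b1 = {s.name: s.beta_std for s in fit1.stats if s.beta_std is not None}
        b2 = {s.name: s.beta_std for s in fit2.stats if s.beta_std is not None}
        for k in b1:
            assert b1[k] == pytest.approx(b2[k], rel=1e-9)

    def test_coverage_monte_carlo(self):
        # planted model at n=452: ~95% CI coverage over 200 replicates
        coeffs = {
            "serial_order": 0.3,
            "weight": 1.0,
            "onset_complexity": -0.5,
            "sonority": 0.2,
            "rise_slope": 0.8,
            "nucleus_dur_s": 4.0,
            "rel_intensity": 1.5,
        }
        hits = 0
        total = 0
        for rep in range(200):
            table = synth_feature_table(452, coeffs, noise_sd=2.0, seed=rep)
            fit = reg.fit_lm(table, "y", list(coeffs), categorical={})
            for s in fit.stats:
                if s.name == "Intercept":
                    continue
                total += 1
                hits += s.ci_low <= coeffs[s.name] <= s.ci_high
        coverage = hits / total
        assert 0.93 <= coverage <= 0.97


class TestBackwardElimination:
    def test_all_significant_final_equals_full(self):
        table = synth_feature_table(
            300, {"sonority": 2.0, "serial_order": -1.0}, noise_sd=0.5, seed=0
        )
        full, final, comp = reg.backward_eliminate(
            table, "y", ["sonority", "serial_order"], categorical={}
        )
        assert final.terms == full.terms
        assert comp.df1 == 0
        assert comp.p == 1.0

    def test_noise_term_eliminated_first(self):
        removed_first = 0
        for seed in range(100):
            table = synth_feature_table(
                200,
                {"sonority": 1.0, "nucleus_dur_s": 8.0, "rel_intensity": 0.0},
                noise_sd=0.8,
                seed=seed,
            )
            full = reg.fit_lm(
                table, "y", ["sonority", "nucleus_dur_s", "rel_intensity"],
                categorical={},
            )
            pvals = {
                t: reg._term_pvalue(full, table, t) for t in full.terms
            }
            removed_first += max(pvals, key=pvals.get) == "rel_intensity"
        assert removed_first >= 90

    def test_null_model_type_i_control(self):
        retained = {t: 0 for t in ("sonority", "serial_order", "rel_intensity")}
        runs = 150
        for seed in range(runs):
            table = synth_feature_table(
                120,
                {t: 0.0 for t in retained},
                noise_sd=1.0,
                seed=seed,
            )
            _, final, _ = reg.backward_eliminate(
                table, "y", list(retained), categorical={}
            )
            for t in final.terms:
                retained[t] += 1
        for t, count in retained.items():
            # each term retained at roughly the alpha=0.05 rate
            assert count / runs < 0.12

    def test_categorical_removed_as_block(self):
        rng = np.random.default_rng(1)
        n = 200
        table = pd.DataFrame(
            {
                "onset_complexity": pd.Categorical(
                    rng.integers(0, 3, n), categories=[0, 1, 2]
                ),
                "sonority": rng.uniform(0, 9, n),
            }
        )
        table["y"] = 2.0 * table["sonority"] + rng.normal(0, 1, n)
        _, final, _ = reg.backward_eliminate(
            table, "y", ["onset_complexity", "sonority"]
        )
        assert "onset_complexity" not in final.terms
        assert "sonority" in final.terms

    def test_final_nested_f_nonnegative(self):
        table = synth_feature_table(
            150,
            {"sonority": 1.0, "serial_order": 0.0, "rel_intensity": 0.0},
            noise_sd=1.0,
            seed=5,
        )
        _, _, comp = reg.backward_eliminate(
            table, "y", ["sonority", "serial_order", "rel_intensity"],
            categorical={},
        )
        assert comp.f >= 0
        assert comp.df1 >= 0


class TestVif:
    def test_orthogonal_predictors_unity(self):
        table = pd.DataFrame(
            {
                "a": [1.0, 1.0, -1.0, -1.0],
                "b": [1.0, -1.0, 1.0, -1.0],
                "y": [0.0, 1.0, 2.0, 3.0],
            }
        )
        out = reg.vif(table, ["a", "b"], categorical={})
        assert out["a"] == pytest.approx(1.0)
        assert out["b"] == pytest.approx(1.0)

    def test_duplicate_column_infinite(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        table["b"] = table["a"]
        out = reg.vif(table, ["a", "b"], categorical={})
        assert np.isinf(out["a"])

    def test_known_correlation_closed_form(self):
        # corr 0.8 -> VIF = 1/(1-0.64) = 2.78
        rng = np.random.default_rng(0)
        n = 20000
        x = rng.normal(size=n)
        z = 0.8 * x + np.sqrt(1 - 0.64) * rng.normal(size=n)
        table = pd.DataFrame({"a": x, "b": z})
        out = reg.vif(table, ["a", "b"], categorical={})
        assert out["a"] == pytest.approx(1.0 / (1.0 - 0.64), rel=0.05)

    def test_matches_statsmodels(self):
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        import statsmodels.api as sm

        table = synth_feature_table(
            120, {"sonority": 1.0, "serial_order": 0.5, "rel_intensity": 0.3},
            noise_sd=1.0, seed=2,
        )
        cols = ["sonority", "serial_order", "rel_intensity"]
        ours = reg.vif(table, cols, categorical={})
        X = sm.add_constant(table[cols].to_numpy())
        for j, c in enumerate(cols):
            theirs = variance_inflation_factor(X, j + 1)
            assert ours[c] == pytest.approx(theirs, rel=1e-8)

    def test_single_column_raises(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            reg.vif(table, ["a"], categorical={})


class TestPredictorCorrelations:
    def test_identical_columns_r_one(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        table["b"] = table["a"]
        r, p, flags = reg.predictor_correlations(table, ["a", "b"])
        assert r.loc["a", "b"] == pytest.approx(1.0)

    def test_anticorrelated_pair_flagged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        table = pd.DataFrame({"a": x, "b": -x + 0.01 * rng.normal(size=200)})
        r, p, flags = reg.predictor_correlations(table, ["a", "b"])
        assert r.loc["a", "b"] < -0.9
        assert flags.loc["a", "b"]

    def test_constant_column_nan_not_flagged(self):
        table = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0, 4.0]})
        r, p, flags = reg.predictor_correlations(table, ["a", "b"])
        assert np.isnan(r.loc["a", "b"])
        assert not flags.loc["a", "b"]

    def test_null_flag_rate(self):
        # independent columns at n=452: flags at ~alpha=0.001
        rng = np.random.default_rng(9)
        flagged = 0
        total = 0
        for _ in range(60):
            table = pd.DataFrame(rng.normal(size=(452, 5)), columns=list("abcde"))
            _, _, flags = reg.predictor_correlations(table, list("abcde"))
            upper = np.triu(flags.to_numpy(), k=1)
            flagged += upper.sum()
            total += 10
        assert flagged / total < 0.01


class TestSyntheticRecoveryEndToEnd:
    def test_zero_noise_exact_recovery(self):
        coeffs = {"sonority": 1.5, "serial_order": -0.3}
        table = synth_feature_table(80, coeffs, noise_sd=0.0, seed=0, intercept=2.0)
        fit = reg.fit_lm(table, "y", list(coeffs), categorical={})
        by_name = {s.name: s for s in fit.stats}
        assert fit.rsquared == pytest.approx(1.0)
        assert by_name["Intercept"].b == pytest.approx(2.0)
        assert by_name["sonority"].b == pytest.approx(1.5)
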