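"""Mixed-model fitting, AIC ranking, parametric bootstrap and the
classical tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from watertrips import metrics, models, segmentation as seg

CFG = seg.SegmentationConfig()


def lmm_steps(
    seed,
    n=1500,
    g=8,
    intercept=0.777,
    b_lin=-0.027,
    b_quad=2.81e-4,
    noise=0.3,
    indiv_sd=0.1,
):
    """Step table drawn directly from the progression-quadratic speed
    model (the within-trip LMM itself, not the path simulator)."""
    rng = np.random.default_rng(seed)
    grp = rng.integers(0, g, n)
    p = rng.uniform(0, 100, n)
    re = rng.normal(0, indiv_sd, g)
    y = intercept + b_lin * p + b_quad * p**2 + re[grp] + rng.normal(0, noise, n)
    return pd.DataFrame(
        {
            "speed_kmh": y,
            "progression_pct": p,
            "dist_water_km": rng.uniform(0, 8, n),
            "duration_h": rng.choice([6.0, 24.0, 48.0, 72.0], n),
            "commuting": rng.integers(0, 2, n).astype(float),
            "individual_id": grp,
        }
    )


def trip_table(seed, n=120, g=8, slope=0.4, commuting_effect=0.0, noise=1.5):
    """Trip-level table with distance = slope * duration + noise."""
    rng = np.random.default_rng(seed)
    grp = rng.integers(0, g, n)
    dur = rng.choice([6.0, 24.0, 48.0, 72.0], n)
    com = rng.integers(0, 2, n).astype(float)
    re = rng.normal(0, 1.0, g)
    y = slope * dur + commuting_effect * com + re[grp] + rng.normal(0, noise, n)
    return pd.DataFrame(
        {
            "distance_km": y,
            "duration_h": dur,
            "commuting": com,
            "trip_type": np.where(com > 0, "commuting", "looping"),
            "individual_id": [f"e{i}" for i in grp],
        }
    )


class TestFitEngine:
    def test_profile_matches_statsmodels_ml(self):
        import statsmodels.api as sm

        df = lmm_steps(3, n=600, g=6)
        spec = models.SPEED_MODEL_SPECS["prog_quadratic"]
        fit = models.fit_lmm(spec, df.assign(
            progression_pct_sq=df.progression_pct**2,
            dist_water_km_sq=df.dist_water_km**2,
        ))
        res = sm.MixedLM(fit.y, fit.X.to_numpy(float), groups=fit.group_codes).fit(
            reml=False
        )
        np.testing.assert_allclose(fit.params.to_numpy(), res.fe_params, atol=2e-3)
        # the profiled solver is an exact ML maximizer: never worse
        assert fit.llf >= res.llf - 1e-3

    def test_aic_identity(self):
        df = lmm_steps(4)
        for fit in models.fit_speed_models(df):
            k = len(fit.params) + 1 + 1  # fixed effects + re variance + residual
            assert fit.aic == pytest.approx(-2.0 * fit.llf + 2.0 * k)
            assert fit.k_params == k

    def test_degenerate_zero_response_flagged(self):
        df = trip_table(0)
        df["distance_km"] = 0.0
        fit = models.fit_lmm(
            models.trip_model_spec("distance_km", random="intercept"), df
        )
        np.testing.assert_allclose(fit.params.to_numpy(), 0.0, atol=1e-10)
        assert "zero residual variance" in fit.notes

    def test_row_order_does_not_change_estimates(self):
        df = trip_table(1)
        spec = models.trip_model_spec("distance_km", random="intercept")
        f1 = models.fit_lmm(spec, df)
        f2 = models.fit_lmm(spec, df.sample(frac=1.0, random_state=7).reset_index(drop=True))
        np.testing.assert_allclose(f1.params.to_numpy(), f2.params.to_numpy(), atol=1e-8)

    def test_duplicated_table_keeps_estimates(self):
        df = lmm_steps(5, n=500)
        spec = models.ModelSpec(
            "m", "speed_kmh", ("intercept", "progression_pct"), "intercept"
        )
        f1 = models.fit_lmm(spec, df)
        f2 = models.fit_lmm(spec, pd.concat([df, df], ignore_index=True))
        np.testing.assert_allclose(f1.params.to_numpy(), f2.params.to_numpy(), atol=1e-3)


class TestTripModel:
    def test_parameter_recovery_duration_slope(self):
        df = trip_table(2, n=160, slope=0.4)
        fit = models.fit_trip_model(df, "distance_km")
        boot = models.parametric_bootstrap(fit, 300, seed=9)
        tab = boot.table.set_index("term")
        assert tab.loc["duration_h", "ci_lo"] < 0.4 < tab.loc["duration_h", "ci_hi"]
        # no commuting effect was simulated
        assert not tab.loc["commuting", "significant"]
        assert not tab.loc["commuting:duration_h", "significant"]

    def test_preconditions(self):
        df = trip_table(0, n=5)
        with pytest.raises(ValueError):
            models.fit_trip_model(df, "distance_km")
        one_ind = trip_table(0, n=40)
        one_ind["individual_id"] = "e0"
        with pytest.raises(ValueError):
            models.fit_trip_model(one_ind, "distance_km")
        with pytest.raises(ValueError):
            models.fit_trip_model(trip_table(0), "not_a_response")


class TestSpeedModelSelection:
    def test_u_shaped_truth_selects_progression_quadratic(self):
        fits = models.fit_speed_models(lmm_steps(6, n=3000))
        assert fits[0].spec.name == "prog_quadratic"
        assert fits[0].aic < fits[1].aic

    def test_candidate_set_and_term_counts(self):
        fits = models.fit_speed_models(lmm_steps(7, n=400))
        names = {f.spec.name for f in fits}
        assert names == {"dist_linear", "dist_quadratic", "prog_linear", "prog_quadratic"}
        by_name = {f.spec.name: f for f in fits}
        assert len(by_name["prog_quadratic"].params) == 12
        assert len(by_name["prog_linear"].params) == 8

    def test_null_simulation_keeps_aics_close(self):
        # speed independent of every covariate: no model should win by a
        # wide margin (complexity penalty differences + sampling noise only)
        rng_spread = []
        for s in (0, 1, 2):
            df = lmm_steps(s, b_lin=0.0, b_quad=0.0)
            fits = models.fit_speed_models(df)
            aics = [f.aic for f in fits]
            rng_spread.append(max(aics) - min(aics))
        assert max(rng_spread) < 25.0

    def test_selection_frequency_increases_with_step_count(self):
        wins = {}
        for n in (200, 800, 3200):
            w = 0
            for s in range(8):
                df = lmm_steps(100 + s, n=n, noise=0.8)
                w += models.fit_speed_models(df)[0].spec.name == "prog_quadratic"
            wins[n] = w
        assert wins[200] <= wins[800] <= wins[3200]
        assert wins[3200] >= 7


class TestParametricBootstrap:
    def test_seed_determinism(self):
        df = trip_table(3)
        fit = models.fit_lmm(models.trip_model_spec("distance_km", "intercept"), df)
        b1 = models.parametric_bootstrap(fit, 50, seed=42)
        b2 = models.parametric_bootstrap(fit, 50, seed=42)
        pd.testing.assert_frame_equal(b1.table, b2.table)

    def test_estimate_inside_own_interval(self):
        df = lmm_steps(8, n=800)
        fit = models.fit_speed_models(df)[0]
        boot = models.parametric_bootstrap(fit, 200, seed=1)
        tab = boot.table
        inside = (tab["ci_lo"] <= tab["estimate"]) & (tab["estimate"] <= tab["ci_hi"])
        assert inside.mean() >= 0.94

    def test_type_one_error_rate_near_nominal(self):
        # a truly zero coefficient should be flagged significant in ~5% of
        # independent pipeline replicates
        def one(seed):
            rng = np.random.default_rng(seed)
            g = rng.integers(0, 6, 120)
            x = rng.uniform(0, 10, 120)
            y = 1.0 + rng.normal(0, 0.5, 120) + rng.normal(0, 0.3, 6)[g]
            df = pd.DataFrame({"y": y, "x": x, "individual_id": g})
            fit = models.fit_lmm(models.ModelSpec("m", "y", ("intercept", "x"), "intercept"), df)
            boot = models.parametric_bootstrap(fit, 200, seed=seed)
            return bool(boot.table.set_index("term").loc["x", "significant"])

        rate = np.mean([one(s) for s in range(200)])
        assert 0.02 <= rate <= 0.08

    def test_ci_width_shrinks_like_root_n(self):
        def width(n, seed):
            df = lmm_steps(seed, n=n)
            fit = models.fit_lmm(
                models.ModelSpec("m", "speed_kmh", ("intercept", "progression_pct"), "intercept"),
                df,
            )
            tab = models.parametric_bootstrap(fit, 300, seed=5).table.set_index("term")
            return tab.loc["progression_pct", "ci_hi"] - tab.loc["progression_pct", "ci_lo"]

        w1 = np.mean([width(500, s) for s in (0, 1, 2)])
        w4 = np.mean([width(2000, s) for s in (0, 1, 2)])
        assert w4 == pytest.approx(w1 / 2.0, rel=0.20)


class TestClassicalTests:
    def test_identical_groups_give_p_one(self):
        d = [6, 24, 24, 48, 48, 72] * 5
        out = models.compare_duration_distributions(d, d)
        assert out["statistic"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_balanced_two_bin_table_statistic_zero(self):
        out = models.compare_duration_distributions([6] * 10 + [24] * 10, [6] * 10 + [24] * 10)
        assert out["statistic"] == pytest.approx(0.0)

    def test_hand_chi_square(self):
        # contingency [[20,5],[5,20]]: chi2 = 18.0, df 1 (no correction)
        loop = [6.0] * 20 + [24.0] * 5
        comm = [6.0] * 5 + [24.0] * 20
        out = models.compare_duration_distributions(loop, comm)
        assert out["statistic"] == pytest.approx(18.0)
        assert out["dof"] == 1

    def test_sparse_bins_are_merged(self):
        loop = [6.0] * 20 + [24.0] * 20 + [90.0]
        comm = [6.0] * 20 + [24.0] * 20
        out = models.compare_duration_distributions(loop, comm)
        assert out["merged_bins"]
        assert len(out["bin_labels"]) == 2

    def test_dry_wet_identical_samples(self):
        s = [0.4, 0.5, 0.6, 0.7]
        out = models.dry_wet_speed_test(s, s)
        assert out["t"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_dry_wet_clear_difference(self):
        rng = np.random.default_rng(0)
        wet = 0.3 + rng.normal(0, 0.01, 50)
        dry = 0.6 + rng.normal(0, 0.01, 50)
        out = models.dry_wet_speed_test(dry, wet)
        assert out["p"] < 0.001
        assert out["mean_dry"] > out["mean_wet"]

    def test_exceedance_counting(self):
        out = models.dry_wet_speed_test([1.0, 1.0], [0.5, 0.9, 1.3])
        assert out["wet_exceedance"][1.0] == pytest.approx(1.0 / 3.0)
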