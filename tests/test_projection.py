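import dataclasses

import numpy as np
import pandas as pd
import pytest

import washcast as wc
from washcast.projection import ConfigurationError


class TestAdjustGdpGrowth:
    def test_zero_coefficient_leaves_growth_unchanged(self):
        assert wc.adjust_gdp_growth(0.03, 0.5, 0.0) == 0.03

    def test_zero_warming_leaves_growth_unchanged(self):
        assert wc.adjust_gdp_growth(0.03, 0.0, -0.005) == 0.03

    def test_hand_arithmetic(self):
        assert wc.adjust_gdp_growth(0.030, 0.5, -0.005) == pytest.approx(0.0275, rel=1e-12)


class TestRecursionsAgainstCumulativeSumOracle:
    def test_coverage_three_years(self):
        vals = wc.project_coverage(0.40, [0.1] * 3, [0.01] * 3, kappa_Y=0.05, kappa_urban=0.2)
        assert vals[-1] == pytest.approx(0.421, rel=1e-12)

    def test_mortality_ten_years(self):
        vals = wc.project_mortality(
            2.0, [0.1] * 10, [0.01] * 10, [0.005] * 10, [0.02] * 10,
            alpha_Y=-0.5, beta_imp=-2.0, beta_piped=-3.0, gamma_temp=0.05,
        )
        assert vals[-1] == pytest.approx(2.0 - 10 * 0.084, rel=1e-12)  # 1.16

    def test_collection_ten_years(self):
        vals = wc.project_collection_time(
            30.0, [0.05] * 10, [0.005] * 10, theta_Y=-1.0, gamma_urban=-10.0
        )
        assert vals[-1] == pytest.approx(29.0, rel=1e-12)

    def test_randomized_constant_drivers_match_closed_form(self):
        """Under constant annual drivers each recursion equals
        baseline + cumulative sum of the per-year increment, pre-bounding."""
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(1, 40))
            dlnY, dU, dT = rng.normal(0, 0.1, 3)
            k = rng.normal(0, 2, 7)
            t = np.arange(1, n + 1)
            cov0 = rng.uniform()
            cov = wc.project_coverage(cov0, [dlnY] * n, [dU] * n, k[0], k[1], clip=False)
            np.testing.assert_allclose(cov, cov0 + t * (k[0] * dlnY + k[1] * dU),
                                       rtol=1e-12, atol=1e-12)
            d0 = rng.uniform(0, 3)
            mort = wc.project_mortality(d0, [dlnY] * n, [dU] * n, [dU] * n, [dT] * n,
                                        k[2], k[3], k[4], gamma_temp=k[5], floor=False)
            oracle = d0 + t * (k[2] * dlnY + k[3] * dU + k[4] * dU + k[5] * dT)
            np.testing.assert_allclose(mort, oracle, rtol=1e-12, atol=1e-12)
            t0 = rng.uniform(0, 60)
            coll = wc.project_collection_time(t0, [dlnY] * n, [dU] * n, k[5], k[6], floor=False)
            np.testing.assert_allclose(coll, t0 + t * (k[5] * dlnY + k[6] * dU), rtol=1e-12, atol=1e-12)

    def test_zero_drivers_give_constant_series(self):
        assert (wc.project_coverage(0.4, [0.0] * 5, [0.0] * 5, 1.0, 1.0) == 0.4).all()
        assert (wc.project_mortality(1.5, *[[0.0] * 5] * 4, -0.5, -2.0, -3.0) == 1.5).all()
        assert (wc.project_collection_time(20.0, [0.0] * 5, [0.0] * 5, -1.0, -1.0) == 20.0).all()


class TestBounds:
    def test_coverage_clips_at_one_and_stays(self):
        vals, flags = wc.project_coverage(0.9, [1.0] * 5, [0.0] * 5, 0.5, 0.0, return_flags=True)
        assert (vals[1:] == 1.0).all() and flags.any()

    def test_mortality_floors_at_zero_and_stays(self):
        vals, flags = wc.project_mortality(
            0.5, [1.0] * 5, [0.0] * 5, [0.0] * 5, [0.0] * 5, -1.0, 0, 0, return_flags=True
        )
        assert (vals == 0.0).all() and flags.all()

    def test_collection_time_floors_at_zero(self):
        vals = wc.project_collection_time(5.0, [1.0] * 4, [0.0] * 4, -10.0, 0.0)
        assert (vals == 0.0).all()


class TestComputeDeaths:
    @pytest.mark.parametrize(
        "rate,pop,expected",
        [(0.0, 1e6, 0.0), (1.5, 2_000_000, 3000.0), (2.0, 0.0, 0.0)],
    )
    def test_examples(self, rate, pop, expected):
        assert wc.compute_deaths(rate, pop) == pytest.approx(expected)


class TestRunProjection:
    def test_zero_elasticities_hold_everything_at_baseline(self, scenario, panel):
        es0 = wc.ElasticitySet.from_values(
            {n: 0.0 for n in ("kappa_Y_improved", "kappa_urban_improved", "kappa_Y_piped",
                              "kappa_urban_piped", "alpha_Y", "beta_imp", "beta_piped",
                              "theta_Y", "gamma_urban")}
        )
        sc = dataclasses.replace(scenario, elasticities=es0)
        res = wc.run_projection(sc, panel)
        base = panel.latest_observed()
        for cid, g in res.frame.groupby("country_id"):
            for col in ("coverage_improved", "coverage_piped", "mortality_wash", "collection_time"):
                np.testing.assert_allclose(g[col], base.loc[cid, col], rtol=1e-12, err_msg=col)

    def test_deaths_identity_holds_at_every_cell(self, projection):
        f = projection.frame
        np.testing.assert_allclose(f["deaths"], f["mortality_wash"] / 1000.0 * f["population"], rtol=1e-12)

    def test_result_respects_all_range_invariants(self, projection):
        f = projection.frame
        assert f["coverage_improved"].between(0, 1).all()
        assert f["coverage_piped"].between(0, 1).all()
        assert (f["coverage_piped"] <= f["coverage_improved"] + 1e-12).all()
        assert f["mortality_wash"].ge(0).all()
        assert f["collection_time"].ge(0).all()

    def test_single_country_composes_the_per_operation_recursions(self, scenario, panel):
        cid = sorted(scenario.paths["country_id"].unique())[0]
        res = wc.run_projection(scenario, panel)
        got = res.country(cid)
        p = scenario.paths[scenario.paths["country_id"] == cid].sort_values("year")
        b = panel.latest_observed().loc[cid]
        es = scenario.elasticities
        g = p["growth_rate"].to_numpy()[1:]
        dU = np.diff(p["urban_share"].to_numpy())
        imp = wc.project_coverage(b["coverage_improved"], g, dU,
                                  es.value("kappa_Y_improved"), es.value("kappa_urban_improved"))
        np.testing.assert_allclose(got["coverage_improved"].to_numpy()[1:], imp, rtol=1e-12)
        coll = wc.project_collection_time(b["collection_time"], g, dU,
                                          es.value("theta_Y"), es.value("gamma_urban"))
        np.testing.assert_allclose(got["collection_time"].to_numpy()[1:], coll, rtol=1e-12)

    def test_row_order_of_inputs_is_irrelevant(self, scenario, panel):
        res1 = wc.run_projection(scenario, panel)
        shuffled = dataclasses.replace(
            scenario, paths=scenario.paths.sample(frac=1.0, random_state=0)
        )
        panel2 = wc.Panel(panel.frame.sample(frac=1.0, random_state=1).reset_index(drop=True))
        res2 = wc.run_projection(shuffled, panel2)
        pd.testing.assert_frame_equal(res1.frame, res2.frame)

    def test_missing_country_named_in_error(self, scenario, panel):
        extra = scenario.paths.copy()
        ghost = extra[extra["country_id"] == extra["country_id"].iloc[0]].assign(country_id="ZZZ")
        sc = dataclasses.replace(scenario, paths=pd.concat([extra, ghost], ignore_index=True))
        with pytest.raises(ConfigurationError, match="ZZZ"):
            wc.run_projection(sc, panel)

    def test_faster_coverage_growth_lowers_mortality_pointwise(self, scenario, panel):
        """With negative coverage-mortality elasticities, uniformly faster
        coverage growth can only reduce the projected mortality path."""
        es_fast = scenario.elasticities.replace_values(
            {"kappa_Y_improved": scenario.elasticities.value("kappa_Y_improved") * 2,
             "kappa_Y_piped": scenario.elasticities.value("kappa_Y_piped") * 2}
        )
        sc_fast = dataclasses.replace(
            scenario, elasticities=es_fast, floor_mortality=False, clip_coverage=False
        )
        sc_base = dataclasses.replace(scenario, floor_mortality=False, clip_coverage=False)
        assert scenario.elasticities.value("beta_imp") < 0
        assert scenario.elasticities.value("beta_piped") < 0
        fast = wc.run_projection(sc_fast, panel).frame
        base = wc.run_projection(sc_base, panel).frame
        assert (fast["mortality_wash"] <= base["mortality_wash"] + 1e-12).all()

    def test_temperature_channel_requires_gamma_temp(self, scenario):
        es = wc.ElasticitySet(dict(scenario.elasticities.coefficients))
        es.coefficients.pop("gamma_temp", None)
        with pytest.raises(ConfigurationError, match="gamma_temp"):
            dataclasses.replace(scenario, elasticities=es, include_temperature_mortality=True)

    def test_level_dy_mode_uses_gdp_level_changes(self, scenario, panel):
        sc = dataclasses.replace(scenario, dy_mode="level")
        res = wc.run_projection(sc, panel)
        # level changes in GDP are hundreds of dollars, so coverage saturates
        assert res.clip_events > 0


def test_group_rate_conserves_total_deaths(projection, panel):
    """Population-weighted group mortality equals group deaths / group
    population: aggregation conserves the deaths total."""
    assignments = wc.classify_projection(projection, panel)
    agg = wc.group_aggregate(projection, assignments, "mortality_wash")
    deaths = wc.group_aggregate(projection, assignments, "deaths")
    implied = deaths["total"] / deaths["population"] * 1000.0
    np.testing.assert_allclose(agg["weighted_mean"], implied, rtol=1e-12)
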