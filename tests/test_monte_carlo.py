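import dataclasses

import numpy as np
import pandas as pd
import pytest

import washcast as wc
from washcast.estimation import PROJECTION_COEFFICIENTS
from washcast.monte_carlo import Dist


@pytest.fixture(scope="module")
def small_world():
    cfg = wc.SynthConfig(n_countries=5, start_year=2000, end_year=2012, horizon_year=2035, seed=9)
    panel = wc.generate_panel(cfg)
    es, _ = wc.fit_all_equations(panel)
    paths = wc.generate_scenario_inputs(cfg)
    scenario = wc.ScenarioConfig(start_year=2012, end_year=2035, paths=paths, elasticities=es)
    valuation = wc.ValuationConfig(vsl_ref=100_000.0, y_ref=2_000.0)
    return panel, es, scenario, valuation


def _fixed_dists(es, n_draws=8, growth=0.037):
    params = {n: Dist.fixed(es.value(n)) for n in PROJECTION_COEFFICIENTS}
    params["f_morb"] = Dist.fixed(0.25)
    return wc.ParameterDistributions(parameters=params, growth=Dist.fixed(growth), n_draws=n_draws)


class TestSampleParameters:
    def test_all_fixed_families_give_identical_rows(self, small_world):
        _, es, *_ = small_world
        draws = wc.sample_parameters(_fixed_dists(es), ["A", "B"], seed=4)
        assert (draws.nunique() == 1).all()
        assert draws.loc[0, "beta_imp"] == es.value("beta_imp")

    def test_growth_draws_match_declared_distribution(self):
        dists = wc.ParameterDistributions(n_draws=1000)
        draws = wc.sample_parameters(dists, ["X"], seed=11)
        g = draws["growth:X"]
        se_mean = 0.013 / np.sqrt(1000)
        assert abs(g.mean() - 0.037) < 3 * se_mean
        se_sd = 0.013 / np.sqrt(2 * (1000 - 1))
        assert abs(g.std(ddof=1) - 0.013) < 3 * se_sd

    def test_same_seed_reproduces_the_matrix(self, small_world):
        _, es, *_ = small_world
        dists = wc.ParameterDistributions.from_elasticities(es, n_draws=20)
        d1 = wc.sample_parameters(dists, ["A", "B"], seed=5)
        d2 = wc.sample_parameters(dists, ["A", "B"], seed=5)
        pd.testing.assert_frame_equal(d1, d2)

    def test_ci_based_draws_stay_inside_the_interval(self, small_world):
        _, es, *_ = small_world
        dists = wc.ParameterDistributions.from_elasticities(es, n_draws=500)
        draws = wc.sample_parameters(dists, [], seed=6)
        for name in PROJECTION_COEFFICIENTS:
            c = es[name]
            assert draws[name].between(c.ci_low, c.ci_high).all(), name

    def test_distribution_validation(self):
        with pytest.raises(ValueError):
            Dist.normal(0.0, -1.0)
        with pytest.raises(ValueError):
            Dist.uniform(1.0, 0.0)
        with pytest.raises(ValueError):
            wc.ParameterDistributions(n_draws=0)


class TestRunEnsemble:
    def test_degenerate_distributions_collapse_onto_base_case(self, small_world):
        panel, es, scenario, valuation = small_world
        growth = float(scenario.paths["growth_rate"].iloc[0])
        # hold growth at each country's own rate by fixing all countries to a
        # single shared rate and giving the base case the same paths
        dists = _fixed_dists(es, n_draws=6, growth=growth)
        summary = wc.run_ensemble(dists, scenario, panel, valuation, seed=2)
        base_paths = scenario.paths.copy()
        base_paths["growth_rate"] = growth
        base = wc.run_projection(dataclasses.replace(scenario, paths=base_paths), panel)
        base_deaths = base.frame.groupby("year")["deaths"].sum()
        q = summary.quantiles("deaths")
        np.testing.assert_allclose(q["q25"], q["q75"], rtol=1e-12)
        np.testing.assert_allclose(q["q50"], base_deaths.to_numpy(), rtol=1e-12)

    def test_seeded_rerun_is_byte_identical(self, small_world):
        panel, es, scenario, valuation = small_world
        dists = wc.ParameterDistributions.from_elasticities(es, n_draws=10)
        s1 = wc.run_ensemble(dists, scenario, panel, valuation, seed=3)
        s2 = wc.run_ensemble(dists, scenario, panel, valuation, seed=3)
        assert s1.draws.to_csv() == s2.draws.to_csv()
        for name in s1.outputs:
            assert s1.quantiles(name).to_csv() == s2.quantiles(name).to_csv()

    def test_wider_growth_uncertainty_widens_the_terminal_band(self, small_world):
        panel, es, scenario, valuation = small_world
        narrow = wc.ParameterDistributions(
            parameters=_fixed_dists(es).parameters, growth=Dist.normal(0.037, 0.005), n_draws=40
        )
        wide = wc.ParameterDistributions(
            parameters=_fixed_dists(es).parameters, growth=Dist.normal(0.037, 0.020), n_draws=40
        )
        qn = wc.run_ensemble(narrow, scenario, panel, valuation, seed=8).quantiles("total_loss")
        qw = wc.run_ensemble(wide, scenario, panel, valuation, seed=8).quantiles("total_loss")
        last = qn.index[-1]
        assert (qw.loc[last, "q75"] - qw.loc[last, "q25"]) > (qn.loc[last, "q75"] - qn.loc[last, "q25"])

    def test_quantiles_are_monotone_in_probability(self, small_world):
        panel, es, scenario, valuation = small_world
        dists = wc.ParameterDistributions.from_elasticities(es, n_draws=25)
        summary = wc.run_ensemble(dists, scenario, panel, valuation, seed=13)
        for name in summary.outputs:
            q = summary.quantiles(name, probs=(0.1, 0.25, 0.5, 0.75, 0.9))
            arr = q.to_numpy()
            assert (np.diff(arr, axis=1) >= -1e-12).all(), name


class TestVarianceDecomposition:
    def test_single_driver_takes_the_whole_share(self):
        rng = np.random.default_rng(0)
        draws = pd.DataFrame({"a": rng.normal(size=2000), "b": rng.normal(size=2000)})
        y = 3.0 * draws["a"].to_numpy() + 0.5
        shares = wc.variance_decomposition(draws, y)
        assert shares["a"] == pytest.approx(1.0, abs=1e-10)
        assert shares["b"] == pytest.approx(0.0, abs=1e-3)

    def test_independent_output_has_no_explained_share(self):
        rng = np.random.default_rng(1)
        draws = pd.DataFrame({"a": rng.normal(size=3000), "b": rng.normal(size=3000)})
        y = rng.normal(size=3000)
        shares = wc.variance_decomposition(draws, y)
        assert shares[["a", "b"]].sum() < 0.01
        assert shares["residual"] > 0.99

    def test_analytic_two_driver_benchmark(self):
        """y = 2a + b with iid standard-normal a, b splits variance 4:1."""
        rng = np.random.default_rng(2)
        draws = pd.DataFrame({"a": rng.normal(size=10_000), "b": rng.normal(size=10_000)})
        y = 2.0 * draws["a"].to_numpy() + draws["b"].to_numpy()
        shares = wc.variance_decomposition(draws, y)
        assert shares["a"] == pytest.approx(0.8, abs=0.02)
        assert shares["b"] == pytest.approx(0.2, abs=0.02)

    def test_shares_sum_to_at_most_one(self):
        rng = np.random.default_rng(3)
        draws = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("abcd"))
        y = draws.sum(axis=1).to_numpy() + rng.normal(size=500)
        shares = wc.variance_decomposition(draws, y)
        assert shares.drop("residual").sum() <= 1.0 + 1e-9

    def test_constant_parameter_gets_zero_share_without_error(self):
        rng = np.random.default_rng(4)
        draws = pd.DataFrame({"a": rng.normal(size=400), "c": np.full(400, 2.5)})
        y = draws["a"].to_numpy()
        shares = wc.variance_decomposition(draws, y)
        assert shares["c"] == 0.0

    def test_collinear_parameters_are_named(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=300)
        draws = pd.DataFrame({"a": a, "twin": 2 * a})
        with pytest.raises(ValueError, match="twin"):
            wc.variance_decomposition(draws, a)
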