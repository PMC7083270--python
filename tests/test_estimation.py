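import numpy as np
import pandas as pd
import pytest

import washcast as wc
from washcast.estimation import EstimationError


def _relerr(a, b):
    return abs(a - b) / abs(b)


@pytest.fixture(scope="module")
def quiet_coverage_panel():
    cfg = wc.SynthConfig(n_countries=30, start_year=2000, end_year=2014, seed=21).with_noise(
        coverage=0.0
    )
    return cfg, wc.generate_panel(cfg)


class TestNoiseFreeRecovery:
    """With the relevant equation's noise at zero, fits recover the
    generator's structural coefficients to at least 6 significant digits."""

    @pytest.mark.parametrize("definition", ["improved", "piped"])
    def test_coverage(self, quiet_coverage_panel, definition):
        cfg, panel = quiet_coverage_panel
        es, report = wc.fit_coverage_model(panel, definition=definition)
        true = cfg.true_elasticities
        for name in (f"kappa0_{definition}", f"kappa_Y_{definition}", f"kappa_urban_{definition}"):
            assert _relerr(es.value(name), true.value(name)) < 1e-6, name
        assert report.n_obs == report.n_countries * 14  # first year lost to the lag

    def test_mortality(self):
        # coverage noise stays on: the coverage regressors need variation of
        # their own, otherwise they are collinear with income and urban share
        cfg = wc.SynthConfig(n_countries=30, start_year=2000, end_year=2014, seed=22).with_noise(
            mortality=0.0
        )
        panel = wc.generate_panel(cfg)
        es, _ = wc.fit_mortality_model(panel)
        true = cfg.true_elasticities
        for name in ("alpha0", "alpha_Y", "beta_imp", "beta_piped", "gamma_temp"):
            assert _relerr(es.value(name), true.value(name)) < 1e-6, name

    def test_collection(self):
        cfg = wc.SynthConfig(n_countries=30, start_year=2000, end_year=2014, seed=23).with_noise(
            collection=0.0
        )
        panel = wc.generate_panel(cfg)
        es, _ = wc.fit_collection_model(panel)
        true = cfg.true_elasticities
        for name in ("theta0", "theta_Y", "gamma_urban"):
            assert _relerr(es.value(name), true.value(name)) < 1e-6, name


def test_matches_brute_force_normal_equations(panel):
    """On a noisy panel the fitted point estimates equal an independent
    least-squares solution of the same design matrix to >= 10 digits."""
    es, _ = wc.fit_collection_model(panel)
    f = panel.frame
    X = np.column_stack([np.ones(len(f)), np.log(f["gdp_pc"]), f["urban_share"]])
    beta, *_ = np.linalg.lstsq(X, f["collection_time"].to_numpy(), rcond=None)
    for got, want in zip((es.value("theta0"), es.value("theta_Y"), es.value("gamma_urban")), beta):
        assert _relerr(got, want) < 1e-10


def test_constant_coverage_yields_zero_elasticities(panel):
    f = panel.frame.copy()
    f["coverage_improved"] = 0.5
    f["coverage_piped"] = 0.2
    es, _ = wc.fit_coverage_model(wc.Panel(f), definition="improved")
    assert es.value("kappa_Y_improved") == pytest.approx(0.0, abs=1e-10)
    assert es.value("kappa_urban_improved") == pytest.approx(0.0, abs=1e-10)


def test_zero_mortality_yields_zero_coefficients(panel):
    f = panel.frame.copy()
    f["mortality_wash"] = 0.0
    es, _ = wc.fit_mortality_model(wc.Panel(f))
    for name in ("alpha0", "alpha_Y", "beta_imp", "beta_piped"):
        assert es.value(name) == pytest.approx(0.0, abs=1e-10)


def test_gamma_temp_absent_when_temperature_uninformative(panel):
    f = panel.frame.copy()
    f["temperature"] = 0.0
    es, _ = wc.fit_mortality_model(wc.Panel(f))
    assert "gamma_temp" not in es
    assert es.external_required == ["gamma_temp"]


def test_collection_translation_changes_only_intercept(panel):
    es0, _ = wc.fit_collection_model(panel)
    f = panel.frame.copy()
    f["collection_time"] = f["collection_time"] + 7.5
    es1, _ = wc.fit_collection_model(wc.Panel(f))
    assert es1.value("theta0") - es0.value("theta0") == pytest.approx(7.5, rel=1e-9)
    assert es1.value("theta_Y") == pytest.approx(es0.value("theta_Y"), rel=1e-9)
    assert es1.value("gamma_urban") == pytest.approx(es0.value("gamma_urban"), rel=1e-9)


def test_all_collection_times_missing_raises(panel):
    f = panel.frame.copy()
    f["collection_time"] = np.nan
    with pytest.raises(EstimationError, match="missing"):
        wc.fit_collection_model(wc.Panel(f))


def test_identical_coverage_columns_warn_of_collinearity(panel):
    f = panel.frame.copy()
    f["coverage_piped"] = f["coverage_improved"]
    with pytest.warns(UserWarning, match="collinear"):
        wc.fit_mortality_model(wc.Panel(f))


def test_controls_enter_the_regression(panel):
    es, report = wc.fit_mortality_model(panel, controls=["fertility", "literacy"])
    assert "ctrl[mortality_wash]:fertility" in es
    assert report.n_obs == len(panel)


@pytest.mark.filterwarnings("ignore::UserWarning", "ignore::Warning")
def test_random_effects_estimator_close_to_pooled_on_clean_panel():
    # noise-free outcome puts the variance components on the boundary, so
    # the MixedLM optimizer warns; point estimates are still exact
    cfg = wc.SynthConfig(n_countries=20, start_year=2000, end_year=2012, seed=31).with_noise(
        collection=0.0
    )
    panel = wc.generate_panel(cfg)
    es_re, rep = wc.fit_collection_model(panel, estimator="random_effects")
    assert rep.estimator == "random_effects"
    true = cfg.true_elasticities
    for name in ("theta_Y", "gamma_urban"):
        assert _relerr(es_re.value(name), true.value(name)) < 1e-4, name


def test_elasticity_set_round_trips_through_json(tmp_path, elasticities):
    path = tmp_path / "es.json"
    elasticities.to_json(path)
    back = wc.ElasticitySet.from_json(path)
    for name, coef in elasticities.coefficients.items():
        assert back[name].value == coef.value
        assert back[name].ci_low == coef.ci_low


def test_ci_brackets_point_estimate(elasticities):
    for name, coef in elasticities.coefficients.items():
        assert coef.ci_low <= coef.value <= coef.ci_high, name


class TestParameterRecoveryStochastic:
    """Bias of each fitted elasticity stays under 10% of truth at
    40 countries x 20 years over repeated noisy generations."""

    def test_coverage_bias(self):
        reps = 40
        ests = []
        for seed in range(reps):
            cfg = wc.SynthConfig(n_countries=40, start_year=1995, end_year=2014, seed=1000 + seed)
            panel = wc.generate_panel(cfg)
            es, _ = wc.fit_coverage_model(panel, definition="improved")
            ests.append(es.value("kappa_Y_improved"))
        true = wc.default_true_elasticities().value("kappa_Y_improved")
        bias = abs(np.mean(ests) - true)
        assert bias < 0.10 * abs(true)
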