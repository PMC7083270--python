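import pytest

import washcast as wc


@pytest.fixture(scope="session")
def synth_config() -> wc.SynthConfig:
    """Small panel: 8 countries, 13 years, default 2050 horizon."""
    return wc.SynthConfig(n_countries=8, start_year=2000, end_year=2012, seed=3)


@pytest.fixture(scope="session")
def panel(synth_config) -> wc.Panel:
    return wc.generate_panel(synth_config)


@pytest.fixture(scope="session")
def elasticities(panel) -> wc.ElasticitySet:
    es, _ = wc.fit_all_equations(panel)
    return es


@pytest.fixture(scope="session")
def scenario(synth_config, elasticities) -> wc.ScenarioConfig:
    paths = wc.generate_scenario_inputs(synth_config)
    return wc.ScenarioConfig(
        start_year=synth_config.end_year,
        end_year=synth_config.horizon_year,
        paths=paths,
        elasticities=elasticities,
    )


@pytest.fixture(scope="session")
def valuation() -> wc.ValuationConfig:
    return wc.ValuationConfig(vsl_ref=100_000.0, y_ref=2_000.0)


@pytest.fixture(scope="session")
def projection(scenario, panel) -> wc.ProjectionResult:
    return wc.run_projection(scenario, panel)


@pytest.fixture(scope="session")
def ledger(projection, valuation, panel) -> wc.LossLedger:
    return wc.compute_loss_ledger(projection, valuation, panel)
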