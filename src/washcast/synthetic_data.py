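"""Synthetic country-year panels with known structural elasticities.

Real inputs to this model (JMP coverage tables, UN population projections,
WHO burden-of-disease mortality, DHS/MICS/WHS collection times) are not
redistributable, so every downstream stage is exercised on panels generated
here, where the true semi-elasticities are user-set and therefore recoverable.

The generator mirrors the structural form of the three estimating equations:

* improved/piped coverage linear in ln *lagged* per-capita GDP and urban
  share (piped from its own coefficients, then capped at improved so the
  nested-definition invariant holds by construction);
* WASH mortality linear in ln GDP, both coverage fractions, and optionally
  temperature;
* one-way collection time linear in ln GDP and urban share.

Noise is additive Gaussian, homoskedastic per equation, with per-equation
standard deviations (set one to zero to make that outcome an exact function
of its regressors). Outcomes are clipped/floored to their physical ranges.
Default magnitudes are chosen to resemble sub-Saharan African conditions:
per-capita GDP of a few hundred to a few thousand 1990 international
dollars, mortality between roughly 0.5 and 3 deaths per 1,000, collection
times of a few to a few tens of minutes, and annual log GDP growth centred
on 3.7% with a 1.3% spread across countries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import CONTROL_PREFIX, Panel
from .estimation import ElasticitySet

__all__ = ["SynthConfig", "ConfigError", "default_true_elasticities",
           "generate_panel", "generate_scenario_inputs"]


class ConfigError(ValueError):
    pass


def default_true_elasticities() -> ElasticitySet:
    """Structural coefficients used when none are supplied.

    Signs follow the model's economics: income and urbanisation raise
    coverage; income and coverage reduce mortality; warming raises it;
    income and urbanisation reduce collection time.
    """
    return ElasticitySet.from_values(
        {
            "kappa0_improved": -0.35,
            "kappa_Y_improved": 0.10,
            "kappa_urban_improved": 0.30,
            "kappa0_piped": -0.45,
            "kappa_Y_piped": 0.08,
            "kappa_urban_piped": 0.25,
            "alpha0": 6.0,
            "alpha_Y": -0.35,
            "beta_imp": -2.0,
            "beta_piped": -1.0,
            "gamma_temp": 0.05,
            "theta0": 70.0,
            "theta_Y": -5.0,
            "gamma_urban": -20.0,
        },
        source="assumed",
    )


@dataclass
class SynthConfig:
    """Generator settings; defaults define the package's study conditions."""

    n_countries: int = 40
    start_year: int = 1995
    end_year: int = 2014
    true_elasticities: ElasticitySet = field(default_factory=default_true_elasticities)
    gdp0_range: tuple[float, float] = (500.0, 5000.0)
    growth_mean: float = 0.037       # annual log growth, SSA 1990-2008 distribution
    growth_sd: float = 0.013
    urban0_range: tuple[float, float] = (0.15, 0.55)
    urban_drift: float = 0.005       # mean urban-share gain per year
    pop0_range: tuple[float, float] = (1e6, 5e7)
    pop_growth_range: tuple[float, float] = (0.015, 0.030)
    temperature_ramp: float = 0.02   # deg C per year, common anomaly path
    #: per-equation Gaussian noise sd: coverage (fraction), mortality
    #: (deaths/1,000), collection time (minutes)
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {"coverage": 0.02, "mortality": 0.10, "collection": 2.0}
    )
    horizon_year: int = 2050
    pop_model: str = "exponential"   # or "logistic"
    seed: int = 0

    def __post_init__(self):
        if self.n_countries < 1:
            raise ConfigError("n_countries must be >= 1")
        if self.end_year <= self.start_year:
            raise ConfigError("end_year must exceed start_year")
        if self.horizon_year <= self.end_year:
            raise ConfigError("horizon_year must exceed end_year")
        for name in ("gdp0_range", "urban0_range", "pop0_range", "pop_growth_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigError(f"{name} is degenerate: ({lo}, {hi})")
        if self.growth_sd < 0:
            raise ConfigError("growth_sd must be >= 0")
        for k, v in self.noise_sd.items():
            if v < 0:
                raise ConfigError(f"noise_sd[{k!r}] must be >= 0")
        if self.pop_model not in ("exponential", "logistic"):
            raise ConfigError(f"unknown pop_model {self.pop_model!r}")

    def with_noise(self, **kw: float) -> "SynthConfig":
        ns = dict(self.noise_sd)
        ns.update(kw)
        return replace(self, noise_sd=ns)


def _rngs(config: SynthConfig) -> tuple[np.random.Generator, ...]:
    """Three independent streams: country attributes, panel noise, scenario.

    Country attributes use their own stream so that a panel and the scenario
    continuing it share the same countries, growth rates, and drifts.
    """
    children = np.random.SeedSequence(config.seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def _country_attributes(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_countries
    lo, hi = config.gdp0_range
    gdp0 = np.exp(rng.uniform(np.log(lo), np.log(hi), n))
    growth = rng.normal(config.growth_mean, config.growth_sd, n)
    urban0 = rng.uniform(*config.urban0_range, n)
    # per-country drift heterogeneity keeps urbanisation from being a pure
    # common time trend (needed for identification)
    urban_drift = config.urban_drift * rng.uniform(0.5, 1.5, n)
    plo, phi = config.pop0_range
    pop0 = np.exp(rng.uniform(np.log(plo), np.log(phi), n))
    pop_growth = rng.uniform(*config.pop_growth_range, n)
    share_b80 = rng.uniform(0.35, 0.55, n)
    hhsize = rng.uniform(3.5, 6.5, n)
    return pd.DataFrame(
        {
            "country_id": [f"C{i:03d}" for i in range(n)],
            "gdp0": gdp0,
            "growth": growth,
            "urban0": urban0,
            "urban_drift": urban_drift,
            "pop0": pop0,
            "pop_growth": pop_growth,
            "income_share_b80": share_b80,
            "household_size": hhsize,
        }
    )


def structural_outcomes(
    ln_gdp: np.ndarray,
    ln_gdp_lag: np.ndarray,
    urban: np.ndarray,
    temperature: np.ndarray,
    elasticities: ElasticitySet,
) -> dict[str, np.ndarray]:
    """Noise-free structural values of the three outcome equations.

    Exposed so tests can recompute the generator's outputs independently of
    the sampling code path.
    """
    e = elasticities.value
    improved = e("kappa0_improved") + e("kappa_Y_improved") * ln_gdp_lag + e("kappa_urban_improved") * urban
    piped = e("kappa0_piped") + e("kappa_Y_piped") * ln_gdp_lag + e("kappa_urban_piped") * urban
    mortality = (
        e("alpha0")
        + e("alpha_Y") * ln_gdp
        + e("beta_imp") * improved
        + e("beta_piped") * piped
        + e("gamma_temp", default=0.0) * temperature
    )
    collection = e("theta0") + e("theta_Y") * ln_gdp + e("gamma_urban") * urban
    return {"improved": improved, "piped": piped, "mortality": mortality, "collection": collection}


def generate_panel(config: SynthConfig) -> Panel:
    """Generate a historical panel with the configured true elasticities.

    The mortality equation is evaluated at the *noisy* coverage realisations,
    so that with mortality noise set to zero the mortality column is an exact
    function of the regressors a fit will see.
    """
    attr_rng, noise_rng, _ = _rngs(config)
    attrs = _country_attributes(config, attr_rng)
    years = np.arange(config.start_year, config.end_year + 1)
    ny = len(years)
    n = config.n_countries

    t = (years - config.start_year)[None, :]                      # (1, ny)
    ln_gdp = np.log(attrs["gdp0"].to_numpy())[:, None] + attrs["growth"].to_numpy()[:, None] * t
    ln_gdp_lag = ln_gdp - attrs["growth"].to_numpy()[:, None]     # one-year lag, exact
    urban = np.clip(
        attrs["urban0"].to_numpy()[:, None] + attrs["urban_drift"].to_numpy()[:, None] * t, 0.0, 1.0
    )
    temperature = np.broadcast_to(config.temperature_ramp * t, (n, ny)).astype(float)
    population = attrs["pop0"].to_numpy()[:, None] * np.exp(attrs["pop_growth"].to_numpy()[:, None] * t)

    sd = config.noise_sd
    e_imp = noise_rng.normal(0.0, sd.get("coverage", 0.0), (n, ny))
    e_pip = noise_rng.normal(0.0, sd.get("coverage", 0.0), (n, ny))
    e_mort = noise_rng.normal(0.0, sd.get("mortality", 0.0), (n, ny))
    e_coll = noise_rng.normal(0.0, sd.get("collection", 0.0), (n, ny))

    e = config.true_elasticities.value
    improved = np.clip(
        e("kappa0_improved") + e("kappa_Y_improved") * ln_gdp_lag
        + e("kappa_urban_improved") * urban + e_imp,
        0.0, 1.0,
    )
    piped = np.clip(
        e("kappa0_piped") + e("kappa_Y_piped") * ln_gdp_lag
        + e("kappa_urban_piped") * urban + e_pip,
        0.0, 1.0,
    )
    piped = np.minimum(piped, improved)  # nested definitions
    mortality = np.maximum(
        e("alpha0") + e("alpha_Y") * ln_gdp + e("beta_imp") * improved
        + e("beta_piped") * piped + e("gamma_temp", default=0.0) * temperature + e_mort,
        0.0,
    )
    collection = np.maximum(
        e("theta0") + e("theta_Y") * ln_gdp + e("gamma_urban") * urban + e_coll,
        0.0,
    )

    fertility = np.clip(noise_rng.normal(5.0, 1.0, (n, ny)), 0.5, None)
    literacy = noise_rng.uniform(0.3, 0.95, (n, ny))
    polity = noise_rng.integers(-10, 11, (n, ny)).astype(float)
    durable = noise_rng.integers(0, 51, (n, ny)).astype(float)
    coup = (noise_rng.uniform(size=(n, ny)) < 0.05).astype(float)

    frame = pd.DataFrame(
        {
            "country_id": np.repeat(attrs["country_id"].to_numpy(), ny),
            "year": np.tile(years, n),
            "gdp_pc": np.exp(ln_gdp).ravel(),
            "population": population.ravel(),
            "urban_share": urban.ravel(),
            "coverage_improved": improved.ravel(),
            "coverage_piped": piped.ravel(),
            "mortality_wash": mortality.ravel(),
            "collection_time": collection.ravel(),
            "temperature": temperature.ravel(),
            "income_share_b80": np.repeat(attrs["income_share_b80"].to_numpy(), ny),
            "household_size": np.repeat(attrs["household_size"].to_numpy(), ny),
            CONTROL_PREFIX + "fertility": fertility.ravel(),
            CONTROL_PREFIX + "literacy": literacy.ravel(),
            CONTROL_PREFIX + "polity": polity.ravel(),
            CONTROL_PREFIX + "durable": durable.ravel(),
            CONTROL_PREFIX + "coup": coup.ravel(),
        }
    )
    return Panel(frame, metadata={"source": "synthetic", "seed": config.seed})


def generate_scenario_inputs(config: SynthConfig) -> pd.DataFrame:
    """Exogenous forecast paths continuing the panel through the horizon.

    Returns a tidy frame (country_id, year, gdp_pc, growth_rate, population,
    urban_share, temperature) from the panel's last year (the projection
    baseline) to ``horizon_year``. GDP grows at each country's constant log
    rate; population grows exponentially or logistically (carrying capacity
    three times the baseline level); urban share continues its drift, capped
    at 1; temperature continues the linear ramp.
    """
    attr_rng, _, _ = _rngs(config)
    attrs = _country_attributes(config, attr_rng)
    years = np.arange(config.end_year, config.horizon_year + 1)
    t_hist = config.end_year - config.start_year
    t = (years - config.end_year)[None, :]
    n = config.n_countries

    ln_gdp_base = np.log(attrs["gdp0"].to_numpy()) + attrs["growth"].to_numpy() * t_hist
    ln_gdp = ln_gdp_base[:, None] + attrs["growth"].to_numpy()[:, None] * t
    growth_rate = np.broadcast_to(attrs["growth"].to_numpy()[:, None], (n, len(years)))

    pop_base = attrs["pop0"].to_numpy() * np.exp(attrs["pop_growth"].to_numpy() * t_hist)
    r = attrs["pop_growth"].to_numpy()[:, None]
    if config.pop_model == "exponential":
        population = pop_base[:, None] * np.exp(r * t)
    else:
        K = 3.0 * pop_base[:, None]
        A = (K - pop_base[:, None]) / pop_base[:, None]
        population = K / (1.0 + A * np.exp(-r * t))

    urban_base = np.clip(
        attrs["urban0"].to_numpy() + attrs["urban_drift"].to_numpy() * t_hist, 0.0, 1.0
    )
    urban = np.clip(urban_base[:, None] + attrs["urban_drift"].to_numpy()[:, None] * t, 0.0, 1.0)
    temperature = np.broadcast_to(
        config.temperature_ramp * (years - config.start_year)[None, :], (n, len(years))
    ).astype(float)

    return pd.DataFrame(
        {
            "country_id": np.repeat(attrs["country_id"].to_numpy(), len(years)),
            "year": np.tile(years, n),
            "gdp_pc": np.exp(ln_gdp).ravel(),
            "growth_rate": growth_rate.ravel(),
            "population": population.ravel(),
            "urban_share": urban.ravel(),
            "temperature": temperature.ravel(),
        }
    )
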