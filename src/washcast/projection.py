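"""Forward recursions: coverage, mortality, collection time, and deaths.

Starting from each country's last observed values, outcomes are stepped one
calendar year at a time by adding elasticity-weighted changes in the drivers:

* coverage[t] = coverage[t-1] + kappa_Y * dlnY[t] + kappa_urban * dUrban[t]
* mortality[t] = mortality[t-1] + alpha_Y * dlnY[t] + beta_imp * dImproved[t]
  + beta_piped * dPiped[t] + gamma_temp * dT[t]
* time[t] = time[t-1] + theta_Y * dlnY[t] + gamma_urban * dUrban[t]

with coverage clipped to [0, 1] (piped additionally capped at improved) and
mortality/collection time floored at 0 after every annual step; every bound
event is flagged. Annual deaths are rate/1,000 x population.

The income driver is the change in ln per-capita GDP, matching the fitted
semi-elasticities (outcome units per log-income unit); ``dy_mode="level"``
switches to the raw level change for sensitivity. GDP growth itself can be
adjusted for a warming path via a growth-per-degree coefficient taken from
the climate-economics literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_model import Panel
from .estimation import ElasticitySet

__all__ = [
    "ScenarioConfig",
    "ProjectionResult",
    "ConfigurationError",
    "adjust_gdp_growth",
    "project_coverage",
    "project_mortality",
    "project_collection_time",
    "compute_deaths",
    "run_projection",
]


class ConfigurationError(ValueError):
    pass


@dataclass
class ScenarioConfig:
    """Exogenous paths and settings for one projection run.

    ``paths`` is a tidy frame with columns ``country_id, year, population,
    urban_share, temperature`` plus ``growth_rate`` (annual log GDP growth)
    and/or ``gdp_pc`` levels, covering every simulated country from its
    baseline year through ``end_year``. ``climate_gdp_coeff`` shifts annual
    log growth by that amount per degree C of annual temperature change.
    """

    start_year: int
    end_year: int
    paths: pd.DataFrame
    elasticities: ElasticitySet
    climate_gdp_coeff: float = 0.0
    include_temperature_mortality: bool = False
    dy_mode: str = "log"
    clip_coverage: bool = True
    floor_mortality: bool = True
    floor_collection_time: bool = True

    def __post_init__(self):
        if self.end_year <= self.start_year:
            raise ConfigurationError("end_year must exceed start_year")
        if self.dy_mode not in ("log", "level"):
            raise ConfigurationError(f"dy_mode must be 'log' or 'level', got {self.dy_mode!r}")
        required = {"country_id", "year", "population", "urban_share", "temperature"}
        missing = required - set(self.paths.columns)
        if missing:
            raise ConfigurationError(f"scenario paths missing column(s): {sorted(missing)}")
        if "growth_rate" not in self.paths.columns and "gdp_pc" not in self.paths.columns:
            raise ConfigurationError("scenario paths need a 'growth_rate' or 'gdp_pc' column")
        if self.include_temperature_mortality and "gamma_temp" not in self.elasticities:
            raise ConfigurationError(
                "include_temperature_mortality requires a gamma_temp coefficient "
                "(supply it externally; it is not fitted from the panel equations)"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, elasticities: ElasticitySet) -> "ScenarioConfig":
        path = Path(path)
        cfg = yaml.safe_load(path.read_text())
        paths_csv = path.parent / cfg.pop("paths_csv")
        paths = pd.read_csv(paths_csv)
        return cls(paths=paths, elasticities=elasticities, **cfg)


@dataclass
class ProjectionResult:
    """Per-(country, year) forecast trajectories.

    ``frame`` columns: country_id, year, forecast (False on the baseline
    row), gdp_pc, population, urban_share, temperature, coverage_improved,
    coverage_piped, mortality_wash (deaths/1,000), deaths (persons/yr),
    collection_time (minutes one-way), clipped (any bound event that year).
    """

    frame: pd.DataFrame
    clip_events: int = 0
    floor_events: int = 0

    def country(self, country_id: str) -> pd.DataFrame:
        return self.frame[self.frame["country_id"] == country_id].reset_index(drop=True)

    def at_year(self, year: int) -> pd.DataFrame:
        return self.frame[self.frame["year"] == year].set_index("country_id")


def adjust_gdp_growth(growth: float, delta_T: float, coeff: float) -> float:
    """Temperature-adjusted annual growth: growth + coeff * delta_T."""
    return growth + coeff * delta_T


def _recurse(
    x0: float,
    increments: np.ndarray,
    lower: float | None,
    upper: float | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sequential accumulation with per-step bounding; returns (values, bound flags)."""
    out = np.empty(len(increments))
    flags = np.zeros(len(increments), dtype=bool)
    prev = x0
    for i, inc in enumerate(increments):
        v = prev + inc
        b = v
        if lower is not None and b < lower:
            b = lower
        if upper is not None and b > upper:
            b = upper
        flags[i] = b != v
        out[i] = b
        prev = b
    return out, flags


def project_coverage(
    cov0: float,
    dlnY: np.ndarray,
    dUrban: np.ndarray,
    kappa_Y: float,
    kappa_urban: float,
    clip: bool = True,
    return_flags: bool = False,
):
    """Coverage recursion; clipped to [0, 1] after each annual step."""
    dlnY = np.asarray(dlnY, float)
    dUrban = np.asarray(dUrban, float)
    if dlnY.shape != dUrban.shape:
        raise ValueError("driver series must have equal length")
    inc = kappa_Y * dlnY + kappa_urban * dUrban
    vals, flags = _recurse(cov0, inc, 0.0 if clip else None, 1.0 if clip else None)
    return (vals, flags) if return_flags else vals


def project_mortality(
    d0: float,
    dlnY: np.ndarray,
    dImproved: np.ndarray,
    dPiped: np.ndarray,
    dT: np.ndarray,
    alpha_Y: float,
    beta_imp: float,
    beta_piped: float,
    gamma_temp: float = 0.0,
    floor: bool = True,
    return_flags: bool = False,
):
    """Mortality-rate recursion; floored at 0 after each annual step."""
    arrays = [np.asarray(a, float) for a in (dlnY, dImproved, dPiped, dT)]
    if len({a.shape for a in arrays}) != 1:
        raise ValueError("driver series must have equal length")
    dlnY, dImp, dPip, dT = arrays
    inc = alpha_Y * dlnY + beta_imp * dImp + beta_piped * dPip + gamma_temp * dT
    vals, flags = _recurse(d0, inc, 0.0 if floor else None, None)
    return (vals, flags) if return_flags else vals


def project_collection_time(
    t0: float,
    dlnY: np.ndarray,
    dUrban: np.ndarray,
    theta_Y: float,
    gamma_urban: float,
    floor: bool = True,
    return_flags: bool = False,
):
    """Collection-time recursion; floored at 0 after each annual step."""
    dlnY = np.asarray(dlnY, float)
    dUrban = np.asarray(dUrban, float)
    if dlnY.shape != dUrban.shape:
        raise ValueError("driver series must have equal length")
    inc = theta_Y * dlnY + gamma_urban * dUrban
    vals, flags = _recurse(t0, inc, 0.0 if floor else None, None)
    return (vals, flags) if return_flags else vals


def compute_deaths(rate, population):
    """Annual deaths from a per-1,000 rate and a population count."""
    return np.asarray(rate, float) / 1000.0 * np.asarray(population, float)


def run_projection(scenario: ScenarioConfig, baseline: Panel) -> ProjectionResult:
    """Run the full recursion system for every country in the scenario.

    The baseline per country is its latest observed panel row; forecasts run
    from the year after that through ``scenario.end_year``. Deterministic
    given inputs, and invariant to the ordering of input rows.
    """
    base = baseline.latest_observed()
    paths = scenario.paths.sort_values(["country_id", "year"])
    countries = sorted(paths["country_id"].unique())
    missing = [c for c in countries if c not in base.index]
    if missing:
        raise ConfigurationError(f"scenario countries missing from baseline panel: {missing}")

    es = scenario.elasticities
    lacking = es.missing_for_projection(
        require_temperature=scenario.include_temperature_mortality
    )
    if lacking:
        raise ConfigurationError(f"elasticity set is missing coefficient(s): {lacking}")
    gamma_temp = (
        es.value("gamma_temp") if scenario.include_temperature_mortality else 0.0
    )

    rows = []
    clip_events = 0
    floor_events = 0
    for cid in countries:
        p = paths[paths["country_id"] == cid]
        b = base.loc[cid]
        base_year = int(b["year"])
        years = np.arange(base_year, scenario.end_year + 1)
        have = set(p["year"].astype(int))
        need = [int(y) for y in years if int(y) not in have]
        if need:
            raise ConfigurationError(
                f"scenario paths for {cid} missing year(s) {need} "
                f"(baseline year {base_year} through {scenario.end_year})"
            )
        p = p[p["year"].isin(years)].set_index("year").reindex(years)

        temp = p["temperature"].to_numpy(float)
        dT = np.diff(temp)
        urban = p["urban_share"].to_numpy(float)
        dUrban = np.diff(urban)

        # GDP path: prefer explicit growth rates, temperature-adjusted
        if "growth_rate" in p.columns and p["growth_rate"].notna().all():
            g = p["growth_rate"].to_numpy(float)[1:]
            g_adj = np.array(
                [adjust_gdp_growth(gi, dTi, scenario.climate_gdp_coeff) for gi, dTi in zip(g, dT)]
            )
            ln_gdp = np.log(float(b["gdp_pc"])) + np.concatenate([[0.0], np.cumsum(g_adj)])
            gdp = np.exp(ln_gdp)
        else:
            gdp_raw = p["gdp_pc"].to_numpy(float)
            g = np.diff(np.log(gdp_raw))
            g_adj = g + scenario.climate_gdp_coeff * dT
            ln_gdp = np.log(float(b["gdp_pc"])) + np.concatenate([[0.0], np.cumsum(g_adj)])
            gdp = np.exp(ln_gdp)

        if scenario.dy_mode == "log":
            dY = np.diff(ln_gdp)
        else:
            dY = np.diff(gdp)

        improved, f1 = project_coverage(
            float(b["coverage_improved"]), dY, dUrban,
            es.value("kappa_Y_improved"), es.value("kappa_urban_improved"),
            clip=scenario.clip_coverage, return_flags=True,
        )
        piped, f2 = project_coverage(
            float(b["coverage_piped"]), dY, dUrban,
            es.value("kappa_Y_piped"), es.value("kappa_urban_piped"),
            clip=scenario.clip_coverage, return_flags=True,
        )
        # nested definitions: piped never exceeds improved
        capped = piped > improved
        piped = np.minimum(piped, improved)
        f2 |= capped

        imp_full = np.concatenate([[float(b["coverage_improved"])], improved])
        pip_full = np.concatenate([[float(b["coverage_piped"])], piped])
        mortality, f3 = project_mortality(
            float(b["mortality_wash"]), dY, np.diff(imp_full), np.diff(pip_full), dT,
            es.value("alpha_Y"), es.value("beta_imp"), es.value("beta_piped"),
            gamma_temp=gamma_temp, floor=scenario.floor_mortality, return_flags=True,
        )
        collection, f4 = project_collection_time(
            float(b["collection_time"]), dY, dUrban,
            es.value("theta_Y"), es.value("gamma_urban"),
            floor=scenario.floor_collection_time, return_flags=True,
        )

        population = p["population"].to_numpy(float)
        mort_full = np.concatenate([[float(b["mortality_wash"])], mortality])
        coll_full = np.concatenate([[float(b["collection_time"])], collection])
        flags_full = np.concatenate([[False], f1 | f2 | f3 | f4])
        clip_events += int((f1 | f2).sum())
        floor_events += int((f3 | f4).sum())

        rows.append(
            pd.DataFrame(
                {
                    "country_id": cid,
                    "year": years,
                    "forecast": years > base_year,
                    "gdp_pc": gdp,
                    "population": population,
                    "urban_share": urban,
                    "temperature": temp,
                    "coverage_improved": imp_full,
                    "coverage_piped": pip_full,
                    "mortality_wash": mort_full,
                    "deaths": compute_deaths(mort_full, population),
                    "collection_time": coll_full,
                    "clipped": flags_full,
                }
            )
        )

    frame = pd.concat(rows, ignore_index=True).sort_values(["country_id", "year"]).reset_index(drop=True)
    return ProjectionResult(frame=frame, clip_events=clip_events, floor_events=floor_events)
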