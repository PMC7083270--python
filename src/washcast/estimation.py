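"""Panel regressions for the three structural associations.

Three reduced-form panel equations drive the forecasting model:

* coverage (improved or piped, as a fraction) on ln lagged per-capita GDP and
  urban share — the coverage semi-elasticities ``kappa_Y`` and ``kappa_urban``;
* WASH mortality rate (deaths/1,000/yr) on ln GDP and both coverage fractions
  — ``alpha_Y``, ``beta_imp``, ``beta_piped`` (plus ``gamma_temp`` when a
  temperature series is supplied);
* one-way collection time (minutes) on ln GDP and urban share — ``theta_Y``
  and ``gamma_urban``.

"Semi-elasticity" here means the outcome stays in natural units while income
enters in logs, so each coefficient is the change in the outcome per unit
change in ln GDP. Outcomes are fit untransformed, coverage in fraction units.

The default estimator is pooled least squares with country-clustered robust
standard errors; a one-way random-effects (random country intercept)
estimator is available via ``estimator="random_effects"``. These regressions
describe associations, not causal effects.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_model import CONTROL_PREFIX, Panel

__all__ = [
    "Coefficient",
    "ElasticitySet",
    "FitReport",
    "EstimationError",
    "fit_coverage_model",
    "fit_mortality_model",
    "fit_collection_model",
]

#: coefficient names the projection recursions consume
PROJECTION_COEFFICIENTS = [
    "kappa_Y_improved",
    "kappa_urban_improved",
    "kappa_Y_piped",
    "kappa_urban_piped",
    "alpha_Y",
    "beta_imp",
    "beta_piped",
    "theta_Y",
    "gamma_urban",
]


class EstimationError(ValueError):
    pass


@dataclass
class Coefficient:
    """Point estimate with uncertainty. ``source`` records provenance:
    ``fitted`` (from a regression here), ``external`` (taken from the
    literature, e.g. the temperature-mortality elasticity), or ``assumed``."""

    value: float
    se: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan
    source: str = "fitted"

    def __post_init__(self):
        if not (math.isnan(self.ci_low) or math.isnan(self.ci_high)):
            if not (self.ci_low - 1e-12 <= self.value <= self.ci_high + 1e-12):
                raise ValueError(
                    f"CI [{self.ci_low}, {self.ci_high}] does not bracket {self.value}"
                )

    def to_dict(self) -> dict:
        return {
            "value": self.value,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "source": self.source,
        }


class ElasticitySet:
    """Named collection of model coefficients with uncertainty.

    Partial sets (one per fitted equation) merge via :meth:`update`; the
    projection stage checks that every coefficient it consumes is present.
    """

    def __init__(self, coefficients: dict[str, Coefficient] | None = None):
        self.coefficients: dict[str, Coefficient] = dict(coefficients or {})

    @classmethod
    def from_values(cls, values: dict[str, float], source: str = "assumed") -> "ElasticitySet":
        return cls({k: Coefficient(value=float(v), source=source) for k, v in values.items()})

    def __getitem__(self, name: str) -> Coefficient:
        return self.coefficients[name]

    def __contains__(self, name: str) -> bool:
        return name in self.coefficients

    def value(self, name: str, default: float | None = None) -> float:
        if name not in self.coefficients:
            if default is not None:
                return default
            raise KeyError(f"coefficient {name!r} not present")
        return self.coefficients[name].value

    def update(self, other: "ElasticitySet") -> "ElasticitySet":
        self.coefficients.update(other.coefficients)
        return self

    def set(self, name: str, value: float, source: str = "assumed") -> None:
        self.coefficients[name] = Coefficient(value=float(value), source=source)

    def replace_values(self, overrides: dict[str, float]) -> "ElasticitySet":
        """New set with point values overridden (uncertainty dropped)."""
        out = {k: Coefficient(value=c.value, se=c.se, ci_low=c.ci_low,
                              ci_high=c.ci_high, source=c.source)
               for k, c in self.coefficients.items()}
        for k, v in overrides.items():
            out[k] = Coefficient(value=float(v), source="sampled")
        return ElasticitySet(out)

    def missing_for_projection(self, require_temperature: bool = False) -> list[str]:
        need = list(PROJECTION_COEFFICIENTS)
        if require_temperature:
            need.append("gamma_temp")
        return [n for n in need if n not in self.coefficients]

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {k: c.to_dict() for k, c in self.coefficients.items()}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "ElasticitySet":
        return cls({k: Coefficient(**v) for k, v in d.items()})

    @classmethod
    def from_json(cls, path: str | Path) -> "ElasticitySet":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def __repr__(self) -> str:
        items = ", ".join(f"{k}={c.value:.4g}" for k, c in sorted(self.coefficients.items()))
        return f"ElasticitySet({items})"


@dataclass
class FitReport:
    """Fit diagnostics: sample size, goodness of fit, and estimates of the
    two error components (idiosyncratic time-varying sd; between-country sd
    of mean residuals)."""

    estimator: str
    n_obs: int
    n_countries: int
    n_dropped: int
    r2: float
    resid_sd: float
    country_effect_sd: float
    condition_number: float = math.nan


def _prepare(
    frame: pd.DataFrame,
    outcome: str,
    regressors: Sequence[str],
    controls: Iterable[str],
) -> tuple[pd.DataFrame, int]:
    ctrl_cols = []
    for c in controls:
        col = c if c in frame.columns else CONTROL_PREFIX + c
        if col not in frame.columns:
            raise EstimationError(f"control column {c!r} not found in panel")
        ctrl_cols.append(col)
    cols = [outcome, *regressors, *ctrl_cols, "country_id"]
    sub = frame[cols]
    n_before = len(sub)
    sub = sub.dropna()
    return sub, n_before - len(sub)


def _fit(
    sub: pd.DataFrame,
    outcome: str,
    regressors: Sequence[str],
    estimator: str,
) -> tuple[dict[str, Coefficient], FitReport]:
    y = sub[outcome].to_numpy(float)
    X = sm.add_constant(sub[list(regressors)].to_numpy(float), has_constant="add")
    names = ["const", *regressors]
    k = X.shape[1]
    if len(y) < k:
        raise EstimationError(
            f"{len(y)} usable observations for {k} coefficients after listwise deletion"
        )
    groups = sub["country_id"].to_numpy()
    n_countries = len(np.unique(groups))
    if estimator == "pooled":
        model = sm.OLS(y, X)
        if n_countries >= 2:
            res = model.fit(cov_type="cluster", cov_kwds={"groups": groups})
        else:
            res = model.fit()
        params, bse, ci = res.params, res.bse, res.conf_int(alpha=0.05)
        r2 = float(res.rsquared)
        resid = res.resid
    elif estimator == "random_effects":
        res = sm.MixedLM(y, X, groups=groups).fit(reml=True)
        params = res.fe_params
        bse = res.bse_fe
        z = 1.959963984540054
        ci = np.column_stack([params - z * bse, params + z * bse])
        fitted = X @ params
        r2 = float(1 - np.var(y - fitted) / np.var(y)) if np.var(y) > 0 else math.nan
        resid = y - fitted
    else:
        raise EstimationError(f"unknown estimator {estimator!r}")

    resid_by_country = pd.Series(np.asarray(resid), index=sub["country_id"].values)
    mu = resid_by_country.groupby(level=0).mean()
    within = resid_by_country - mu.reindex(resid_by_country.index).to_numpy()
    report = FitReport(
        estimator=estimator,
        n_obs=len(y),
        n_countries=n_countries,
        n_dropped=0,  # filled by caller
        r2=r2,
        resid_sd=float(np.std(within, ddof=1)) if len(within) > 1 else math.nan,
        country_effect_sd=float(np.std(mu, ddof=1)) if len(mu) > 1 else math.nan,
        condition_number=float(np.linalg.cond(X)),
    )
    coeffs = {}
    ci = np.asarray(ci)
    for i, nm in enumerate(names):
        lo, hi = float(ci[i, 0]), float(ci[i, 1])
        coeffs[nm] = Coefficient(
            value=float(params[i]), se=float(bse[i]), ci_low=lo, ci_high=hi, source="fitted"
        )
    return coeffs, report


def _with_lagged_income(frame: pd.DataFrame) -> pd.DataFrame:
    df = frame.sort_values(["country_id", "year"]).copy()
    df["ln_gdp"] = np.log(df["gdp_pc"])
    # lag is exactly one panel period within country
    df["ln_gdp_lag"] = df.groupby("country_id")["ln_gdp"].shift(1)
    return df


def fit_coverage_model(
    panel: Panel,
    definition: str = "improved",
    controls: Iterable[str] = (),
    estimator: str = "pooled",
) -> tuple[ElasticitySet, FitReport]:
    """Fit the coverage equation for one coverage definition.

    Coverage (fraction) is regressed on ln lagged per-capita GDP and urban
    share, plus any named controls. Returns a partial :class:`ElasticitySet`
    with ``kappa0_<def>``, ``kappa_Y_<def>`` and ``kappa_urban_<def>``.
    """
    if definition not in ("improved", "piped"):
        raise EstimationError(f"definition must be 'improved' or 'piped', got {definition!r}")
    df = _with_lagged_income(panel.frame)
    outcome = f"coverage_{definition}"
    sub, dropped = _prepare(df, outcome, ["ln_gdp_lag", "urban_share"], controls)
    counts = sub.groupby("country_id").size()
    if (counts < 1).all() or sub.empty:
        raise EstimationError("no usable observations after lag construction")
    coeffs, report = _fit(sub, outcome, ["ln_gdp_lag", "urban_share",
                                         *[c if c in sub.columns else CONTROL_PREFIX + c for c in controls]],
                          estimator)
    report.n_dropped = dropped
    es = ElasticitySet(
        {
            f"kappa0_{definition}": coeffs["const"],
            f"kappa_Y_{definition}": coeffs["ln_gdp_lag"],
            f"kappa_urban_{definition}": coeffs["urban_share"],
        }
    )
    for c in controls:
        col = c if c in sub.columns else CONTROL_PREFIX + c
        es.coefficients[f"ctrl[{outcome}]:{c}"] = coeffs[col]
    return es, report


def fit_mortality_model(
    panel: Panel,
    controls: Iterable[str] = (),
    estimator: str = "pooled",
    include_temperature: bool | None = None,
) -> tuple[ElasticitySet, FitReport]:
    """Fit the mortality equation.

    The WASH mortality rate (deaths/1,000/yr) is regressed on ln per-capita
    GDP and both coverage fractions. Temperature is included only when the
    panel carries an informative temperature series (``include_temperature``
    overrides the auto-detection); otherwise ``gamma_temp`` is absent from
    the result and must be supplied externally before projection with a
    temperature channel.
    """
    df = panel.frame.copy()
    df["ln_gdp"] = np.log(df["gdp_pc"])
    temp = df["temperature"]
    if include_temperature is None:
        include_temperature = temp.notna().any() and temp.dropna().nunique() > 1
    regressors = ["ln_gdp", "coverage_improved", "coverage_piped"]
    if include_temperature:
        regressors.append("temperature")
    sub, dropped = _prepare(df, "mortality_wash", regressors, controls)
    if sub.empty:
        raise EstimationError("no usable observations for the mortality equation")
    corr = sub["coverage_improved"].corr(sub["coverage_piped"])
    full_regs = regressors + [c if c in sub.columns else CONTROL_PREFIX + c for c in controls]
    coeffs, report = _fit(sub, "mortality_wash", full_regs, estimator)
    report.n_dropped = dropped
    if abs(corr) > 0.999 or report.condition_number > 1e8:
        warnings.warn(
            "improved and piped coverage are nearly collinear "
            f"(corr={corr:.6f}, condition number={report.condition_number:.3g}); "
            "beta_imp and beta_piped are not separately identified",
            stacklevel=2,
        )
    mapping = {
        "alpha0": coeffs["const"],
        "alpha_Y": coeffs["ln_gdp"],
        "beta_imp": coeffs["coverage_improved"],
        "beta_piped": coeffs["coverage_piped"],
    }
    if include_temperature:
        mapping["gamma_temp"] = coeffs["temperature"]
    es = ElasticitySet(mapping)
    if not include_temperature:
        # caller must source the temperature elasticity from the literature
        es.external_required = ["gamma_temp"]
    for c in controls:
        col = c if c in sub.columns else CONTROL_PREFIX + c
        es.coefficients[f"ctrl[mortality_wash]:{c}"] = coeffs[col]
    return es, report


def fit_collection_model(
    panel: Panel,
    controls: Iterable[str] = (),
    estimator: str = "pooled",
) -> tuple[ElasticitySet, FitReport]:
    """Fit the collection-time equation.

    One-way collection time (minutes) is regressed on ln per-capita GDP and
    urban share; survey-source indicator variables (DHS/MICS/WHS) enter as
    ordinary named controls.
    """
    df = panel.frame.copy()
    if df["collection_time"].dropna().empty:
        raise EstimationError("all collection times are missing")
    df["ln_gdp"] = np.log(df["gdp_pc"])
    sub, dropped = _prepare(df, "collection_time", ["ln_gdp", "urban_share"], controls)
    if sub.empty:
        raise EstimationError("no usable observations for the collection-time equation")
    full_regs = ["ln_gdp", "urban_share"] + [
        c if c in sub.columns else CONTROL_PREFIX + c for c in controls
    ]
    coeffs, report = _fit(sub, "collection_time", full_regs, estimator)
    report.n_dropped = dropped
    es = ElasticitySet(
        {
            "theta0": coeffs["const"],
            "theta_Y": coeffs["ln_gdp"],
            "gamma_urban": coeffs["urban_share"],
        }
    )
    for c in controls:
        col = c if c in sub.columns else CONTROL_PREFIX + c
        es.coefficients[f"ctrl[collection_time]:{c}"] = coeffs[col]
    return es, report
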