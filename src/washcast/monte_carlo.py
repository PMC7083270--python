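"""Monte Carlo uncertainty propagation and variance decomposition.

Each draw samples the uncertain inputs — per-country average annual GDP
growth rates (default N(3.7%, 1.3%), the historical cross-country spread of
sub-Saharan growth), the fitted semi-elasticities (normal with sd implied by
their 95% confidence intervals, truncated to those intervals), the
growth-per-degree climate coefficient, and the morbidity fraction — then
reruns the full projection + valuation pipeline and records aggregate output
trajectories. Ensembles are summarised by per-year quantiles (interquartile
bands by default) and by a variance decomposition attributing output
variance to each sampled parameter via squared standardized regression
coefficients (SRC), an R-squared-style share suited to near-linear
simulators; the unexplained remainder is reported as a residual share.

Growth draws are per-country and held constant over the horizon within a
draw. All sampling is reproducible from a single integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import Panel
from .estimation import PROJECTION_COEFFICIENTS, ElasticitySet
from .losses import ValuationConfig, compute_loss_ledger
from .projection import ProjectionResult, ScenarioConfig, run_projection

__all__ = [
    "Dist",
    "ParameterDistributions",
    "EnsembleSummary",
    "sample_parameters",
    "run_ensemble",
    "variance_decomposition",
]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class Dist:
    """One-dimensional sampling distribution for a scalar parameter."""

    family: str          # fixed | normal | uniform | triangular | truncnorm
    params: tuple[float, ...]

    @classmethod
    def fixed(cls, value: float) -> "Dist":
        return cls("fixed", (float(value),))

    @classmethod
    def normal(cls, mean: float, sd: float) -> "Dist":
        if sd < 0:
            raise ValueError("sd must be >= 0")
        return cls("normal", (float(mean), float(sd)))

    @classmethod
    def uniform(cls, low: float, high: float) -> "Dist":
        if high < low:
            raise ValueError("bounds must be ordered")
        return cls("uniform", (float(low), float(high)))

    @classmethod
    def triangular(cls, low: float, mode: float, high: float) -> "Dist":
        if not low <= mode <= high:
            raise ValueError("require low <= mode <= high")
        return cls("triangular", (float(low), float(mode), float(high)))

    @classmethod
    def truncnorm(cls, mean: float, sd: float, low: float, high: float) -> "Dist":
        if sd < 0:
            raise ValueError("sd must be >= 0")
        if high < low:
            raise ValueError("bounds must be ordered")
        return cls("truncnorm", (float(mean), float(sd), float(low), float(high)))

    @classmethod
    def from_ci(cls, value: float, ci_low: float, ci_high: float) -> "Dist":
        """Normal implied by a 95% CI, truncated to that CI."""
        sd = (ci_high - ci_low) / (2.0 * _Z95)
        if sd == 0:
            return cls.fixed(value)
        return cls.truncnorm(value, sd, ci_low, ci_high)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        f, p = self.family, self.params
        if f == "fixed":
            return np.full(size, p[0])
        if f == "normal":
            return rng.normal(p[0], p[1], size)
        if f == "uniform":
            return rng.uniform(p[0], p[1], size)
        if f == "triangular":
            return rng.triangular(p[0], p[1], p[2], size)
        if f == "truncnorm":
            mean, sd, lo, hi = p
            if sd == 0:
                return np.full(size, mean)
            a, b = (lo - mean) / sd, (hi - mean) / sd
            u = rng.uniform(size=size)
            return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)
        raise ValueError(f"unknown distribution family {f!r}")


@dataclass
class ParameterDistributions:
    """Sampling plan for one ensemble.

    ``parameters`` maps coefficient/assumption names (elasticities,
    ``f_morb``, ``climate_gdp_coeff``) to distributions; ``growth`` is
    sampled independently per country.
    """

    parameters: dict[str, Dist] = field(default_factory=dict)
    growth: Dist = field(default_factory=lambda: Dist.normal(0.037, 0.013))
    n_draws: int = 1000

    def __post_init__(self):
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")

    @classmethod
    def from_elasticities(
        cls,
        elasticities: ElasticitySet,
        names: list[str] | None = None,
        f_morb_bounds: tuple[float, float] = (0.10, 0.40),
        climate_gdp_coeff: Dist | None = None,
        growth: Dist | None = None,
        n_draws: int = 1000,
    ) -> "ParameterDistributions":
        """CI-based sampling plan: every named fitted coefficient varies over
        its 95% confidence interval; the morbidity fraction is uniform over
        its sensitivity bounds."""
        names = list(names or PROJECTION_COEFFICIENTS)
        params: dict[str, Dist] = {}
        for n in names:
            if n not in elasticities:
                continue
            c = elasticities[n]
            if np.isfinite(c.ci_low) and np.isfinite(c.ci_high) and c.ci_high > c.ci_low:
                params[n] = Dist.from_ci(c.value, c.ci_low, c.ci_high)
            else:
                params[n] = Dist.fixed(c.value)
        params["f_morb"] = Dist.uniform(*f_morb_bounds)
        if climate_gdp_coeff is not None:
            params["climate_gdp_coeff"] = climate_gdp_coeff
        kw = {} if growth is None else {"growth": growth}
        return cls(parameters=params, n_draws=n_draws, **kw)


def sample_parameters(
    dists: ParameterDistributions,
    countries: list[str],
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw the parameter matrix: one row per realisation.

    Columns are the named parameters plus one ``growth:<country>`` column per
    country (growth rates are independent across countries).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = dists.n_draws
    cols: dict[str, np.ndarray] = {}
    for name in sorted(dists.parameters):
        cols[name] = dists.parameters[name].sample(rng, n)
    for cid in countries:
        cols[f"growth:{cid}"] = dists.growth.sample(rng, n)
    return pd.DataFrame(cols)


@dataclass
class EnsembleSummary:
    """Draws, per-draw aggregate output trajectories, and summaries."""

    draws: pd.DataFrame
    years: np.ndarray
    outputs: dict[str, np.ndarray]       # name -> (n_successful_draws, n_years)
    draw_ok: np.ndarray                  # bool per draw
    failures: list[tuple[int, str]] = field(default_factory=list)

    def quantiles(self, output: str, probs=(0.25, 0.5, 0.75)) -> pd.DataFrame:
        """Pointwise per-year ensemble quantiles of one output."""
        arr = self.outputs[output]
        q = np.quantile(arr, probs, axis=0)
        return pd.DataFrame(
            q.T, index=pd.Index(self.years, name="year"),
            columns=[f"q{int(round(p * 100))}" for p in probs],
        )

    def variance_shares(self, output: str, year: int | None = None) -> pd.Series:
        """SRC variance decomposition of one output at one year (default:
        the terminal year)."""
        arr = self.outputs[output]
        years = list(self.years)
        j = len(years) - 1 if year is None else years.index(year)
        return variance_decomposition(self.draws[self.draw_ok], arr[:, j])


#: aggregate outputs recorded per draw: (name, source, how)
_ENSEMBLE_OUTPUTS = [
    ("mortality_wash", "projection", "pop_weighted_mean"),
    ("deaths", "projection", "sum"),
    ("collection_time", "projection", "pop_weighted_mean"),
    ("coverage_improved", "projection", "pop_weighted_mean"),
    ("health_loss", "losses", "sum"),
    ("time_loss", "losses", "sum"),
    ("total_loss", "losses", "sum"),
]


def _aggregate_outputs(result: ProjectionResult, ledger_frame: pd.DataFrame) -> pd.DataFrame:
    proj = result.frame
    out = {}
    for name, source, how in _ENSEMBLE_OUTPUTS:
        df = proj if source == "projection" else ledger_frame
        if how == "sum":
            series = df.groupby("year")[name].sum()
        else:
            weighted = df[name] * df["population"]
            series = weighted.groupby(df["year"]).sum() / df.groupby("year")["population"].sum()
        out[name] = series
    return pd.DataFrame(out)


def run_ensemble(
    dists: ParameterDistributions,
    scenario: ScenarioConfig,
    baseline: Panel,
    valuation: ValuationConfig,
    seed: int = 0,
) -> EnsembleSummary:
    """Sample parameters, rerun projection + valuation per draw, summarise.

    Per draw the sampled elasticities override the scenario's point
    estimates, per-country growth rates replace the scenario growth paths
    (constant within the draw), and sampled ``f_morb``/``climate_gdp_coeff``
    override the valuation/climate assumptions. A draw that fails is
    recorded in ``failures`` with its exception and skipped, never silently
    dropped.
    """
    countries = sorted(scenario.paths["country_id"].unique())
    draws = sample_parameters(dists, countries, seed)
    elast_names = [c for c in draws.columns if c in scenario.elasticities or c == "gamma_temp"]

    per_draw: list[pd.DataFrame] = []
    ok = np.zeros(len(draws), dtype=bool)
    failures: list[tuple[int, str]] = []
    years = None
    for i, row in draws.iterrows():
        try:
            es = scenario.elasticities.replace_values(
                {n: row[n] for n in elast_names if n in row.index}
            )
            paths = scenario.paths.copy()
            growth_map = {cid: row[f"growth:{cid}"] for cid in countries}
            paths["growth_rate"] = paths["country_id"].map(growth_map)
            sc = dc_replace(
                scenario,
                paths=paths,
                elasticities=es,
                climate_gdp_coeff=float(row.get("climate_gdp_coeff", scenario.climate_gdp_coeff)),
            )
            val = dc_replace(valuation, f_morb=float(row.get("f_morb", valuation.f_morb)))
            result = run_projection(sc, baseline)
            ledger = compute_loss_ledger(result, val, baseline)
            agg = _aggregate_outputs(result, ledger.frame)
            if years is None:
                years = agg.index.to_numpy()
            per_draw.append(agg)
            ok[i] = True
        except Exception as exc:  # noqa: BLE001 — single-draw failures are survivable
            failures.append((int(i), f"{type(exc).__name__}: {exc}"))
            warnings.warn(f"draw {i} failed and was skipped: {exc}", stacklevel=2)
    if not per_draw:
        raise RuntimeError("every Monte Carlo draw failed")
    outputs = {
        name: np.vstack([d[name].to_numpy() for d in per_draw])
        for name, _, _ in _ENSEMBLE_OUTPUTS
    }
    return EnsembleSummary(draws=draws, years=years, outputs=outputs, draw_ok=ok, failures=failures)


def variance_decomposition(draws: pd.DataFrame, output: np.ndarray) -> pd.Series:
    """Attribute output variance to sampled parameters via squared SRCs.

    Regresses the (standardized) output on the standardized draws; each
    parameter's share is its squared standardized coefficient, and the
    unexplained remainder is returned under ``residual``. Constant
    (degenerate) parameters contribute a zero share. Raises if the varying
    draws are rank-deficient, naming the collinear parameters.
    """
    output = np.asarray(output, float)
    if len(draws) != len(output):
        raise ValueError("draws and output must align row-wise")
    if len(draws) <= draws.shape[1]:
        raise ValueError("need more draws than parameters for the decomposition")
    shares = pd.Series(0.0, index=list(draws.columns) + ["residual"])
    sd_y = output.std(ddof=1)
    if sd_y == 0:
        return shares
    X = draws.to_numpy(float)
    sd_x = X.std(axis=0, ddof=1)
    varying = sd_x > 0
    names = [c for c, v in zip(draws.columns, varying) if v]
    if not names:
        shares["residual"] = 1.0
        return shares
    Xs = (X[:, varying] - X[:, varying].mean(axis=0)) / sd_x[varying]
    if np.linalg.matrix_rank(Xs) < Xs.shape[1]:
        corr = np.corrcoef(Xs, rowvar=False)
        pairs = [
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
            if abs(corr[i, j]) > 0.9999
        ]
        raise ValueError(f"rank-deficient parameter draws; collinear: {pairs or names}")
    ys = (output - output.mean()) / sd_y
    b, *_ = np.linalg.lstsq(np.column_stack([np.ones(len(ys)), Xs]), ys, rcond=None)
    src = b[1:]
    for name, s in zip(names, src):
        shares[name] = s**2
    resid = ys - np.column_stack([np.ones(len(ys)), Xs]) @ b
    shares["residual"] = max(0.0, float(np.var(resid, ddof=0) / np.var(ys, ddof=0)))
    return shares
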