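"""End-to-end pipeline orchestration and report rendering.

``run_pipeline`` wires the stages — estimate (optional), project, value
losses, classify, aggregate, Monte Carlo (optional) — reading the
configuration files named in a :class:`RunConfig` and writing every stage's
CSV plus a machine-readable run manifest (inputs, seed, package version,
clip/floor audit counts, per-stage timings) into the output directory.
``render_report`` turns a finished artifact directory into per-group summary
tables and trajectory plots with observed/forecast shading.

All randomness flows from the single top-level seed, fanned out to named
substreams, so two runs with identical config and seed produce byte-identical
numeric outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import Panel, read_panel
from .estimation import (
    ElasticitySet,
    fit_collection_model,
    fit_coverage_model,
    fit_mortality_model,
)
from .grouping import GroupThresholds, classify_projection, group_aggregate
from .losses import ValuationConfig, compute_loss_ledger
from .monte_carlo import Dist, ParameterDistributions, run_ensemble
from .projection import ScenarioConfig, run_projection

__all__ = ["RunConfig", "run_pipeline", "render_report", "fit_all_equations"]

#: fields reported per group in tables and plots
REPORT_FIELDS = [
    ("projections.csv", "mortality_wash"),
    ("projections.csv", "deaths"),
    ("projections.csv", "collection_time"),
    ("losses.csv", "health_loss"),
    ("losses.csv", "time_loss"),
    ("losses.csv", "total_loss"),
]


@dataclass
class RunConfig:
    """File-path wiring for one pipeline run."""

    panel: Path
    scenario: Path
    valuation: Path
    out_dir: Path
    elasticities: Path | None = None     # fit from the panel when absent
    thresholds: Path | None = None
    seed: int = 0
    monte_carlo: bool = False
    n_draws: int = 1000
    controls: list[str] = field(default_factory=list)

    def __post_init__(self):
        for name in ("panel", "scenario", "valuation"):
            p = Path(getattr(self, name))
            setattr(self, name, p)
            if not p.exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        for name in ("elasticities", "thresholds"):
            p = getattr(self, name)
            if p is not None:
                p = Path(p)
                setattr(self, name, p)
                if not p.exists():
                    raise FileNotFoundError(f"{name} file not found: {p}")
        self.out_dir = Path(self.out_dir)


def fit_all_equations(
    panel: Panel, controls: list[str] | None = None
) -> tuple[ElasticitySet, dict]:
    """Fit the coverage (both definitions), mortality, and collection-time
    equations and merge the partial coefficient sets."""
    controls = controls or []
    es = ElasticitySet()
    reports = {}
    for definition in ("improved", "piped"):
        part, rep = fit_coverage_model(panel, definition=definition, controls=controls)
        es.update(part)
        reports[f"coverage_{definition}"] = rep
    part, rep = fit_mortality_model(panel, controls=controls)
    es.update(part)
    reports["mortality"] = rep
    part, rep = fit_collection_model(panel, controls=controls)
    es.update(part)
    reports["collection"] = rep
    return es, reports


def _write_csv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, index=index, float_format="%.12g")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the artifact directory.

    Any stage failure aborts with the stage name and cause; files written by
    completed stages are left in place and flagged partial in the manifest.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "washcast",
        "version": __version__,
        "seed": config.seed,
        "inputs": {
            "panel": str(config.panel),
            "scenario": str(config.scenario),
            "valuation": str(config.valuation),
            "elasticities": str(config.elasticities) if config.elasticities else None,
            "thresholds": str(config.thresholds) if config.thresholds else None,
        },
        "stages": {},
        "complete": False,
    }
    stage = "read inputs"
    try:
        t0 = time.perf_counter()
        panel = read_panel(config.panel)
        valuation = ValuationConfig(**yaml.safe_load(config.valuation.read_text()))
        thresholds = (
            GroupThresholds(**yaml.safe_load(config.thresholds.read_text()))
            if config.thresholds
            else GroupThresholds()
        )
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0}

        stage = "estimate"
        t0 = time.perf_counter()
        if config.elasticities:
            es = ElasticitySet.from_json(config.elasticities)
        else:
            es, reports = fit_all_equations(panel, config.controls)
            manifest["stages"][stage] = {
                name: {"n_obs": r.n_obs, "r2": r.r2} for name, r in reports.items()
            }
        es.to_json(out / "elasticities.json")
        manifest["stages"].setdefault(stage, {})["seconds"] = time.perf_counter() - t0

        stage = "project"
        t0 = time.perf_counter()
        scenario = ScenarioConfig.from_yaml(config.scenario, es)
        result = run_projection(scenario, panel)
        _write_csv(result.frame, out / "projections.csv")
        manifest["stages"][stage] = {
            "seconds": time.perf_counter() - t0,
            "clip_events": result.clip_events,
            "floor_events": result.floor_events,
        }

        stage = "losses"
        t0 = time.perf_counter()
        ledger = compute_loss_ledger(result, valuation, panel)
        _write_csv(ledger.frame, out / "losses.csv")
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0}

        stage = "classify"
        t0 = time.perf_counter()
        assignments = classify_projection(result, panel, thresholds)
        groups = pd.DataFrame(
            [
                {
                    "country_id": a.country_id,
                    "group": a.group,
                    "baseline_rate": a.baseline_rate,
                    "terminal_rate": a.terminal_rate,
                }
                for a in assignments
            ]
        )
        _write_csv(groups, out / "groups.csv")
        series = []
        merged = result.frame.merge(
            ledger.frame[["country_id", "year", "health_loss", "time_loss", "total_loss"]],
            on=["country_id", "year"],
        )
        for f in ("mortality_wash", "deaths", "collection_time",
                  "health_loss", "time_loss", "total_loss"):
            agg = group_aggregate(merged, assignments, f).reset_index()
            agg.insert(0, "field", f)
            series.append(agg)
        _write_csv(pd.concat(series, ignore_index=True), out / "group_series.csv")
        manifest["stages"][stage] = {
            "seconds": time.perf_counter() - t0,
            "n_groups": int(groups["group"].nunique()),
        }

        if config.monte_carlo:
            stage = "montecarlo"
            t0 = time.perf_counter()
            mc_dir = out / "ensemble"
            mc_dir.mkdir(exist_ok=True)
            dists = ParameterDistributions.from_elasticities(
                es,
                climate_gdp_coeff=Dist.fixed(scenario.climate_gdp_coeff),
                n_draws=config.n_draws,
            )
            # substream: keep ensemble sampling independent of any other use
            mc_seed = int(np.random.SeedSequence(config.seed).spawn(4)[3].generate_state(1)[0] % (2**31))
            summary = run_ensemble(dists, scenario, panel, valuation, seed=mc_seed)
            _write_csv(summary.draws, mc_dir / "draws.csv")
            for name in summary.outputs:
                _write_csv(summary.quantiles(name), mc_dir / f"quantiles_{name}.csv", index=True)
            if int(summary.draw_ok.sum()) > summary.draws.shape[1]:
                shares = summary.variance_shares("mortality_wash")
            else:
                # under-determined: fewer successful draws than parameters
                shares = pd.Series(
                    np.nan, index=list(summary.draws.columns) + ["residual"]
                )
            shares.rename_axis("parameter").to_frame("share").to_csv(
                mc_dir / "variance_shares.csv", float_format="%.12g"
            )
            manifest["stages"][stage] = {
                "seconds": time.perf_counter() - t0,
                "n_draws": config.n_draws,
                "n_failures": len(summary.failures),
            }
        manifest["complete"] = True
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def render_report(artifact_dir: str | Path, plots: bool = True) -> Path:
    """Render per-group tables (and plots) from a finished pipeline run.

    Missing series are listed in ``report/NOTES.txt`` and the report is still
    produced; absent Monte Carlo output just omits the uncertainty bands.
    """
    artifact_dir = Path(artifact_dir)
    report_dir = artifact_dir / "report"
    report_dir.mkdir(exist_ok=True)
    notes: list[str] = []

    series_path = artifact_dir / "group_series.csv"
    if not series_path.exists():
        raise FileNotFoundError(f"missing pipeline output: {series_path}")
    series = pd.read_csv(series_path)
    proj = pd.read_csv(artifact_dir / "projections.csv")
    have_fields = set(series["field"].unique())

    for _, f in REPORT_FIELDS:
        if f not in have_fields:
            notes.append(f"series {f!r} missing from group_series.csv; omitted")
            continue
        sub = series[series["field"] == f]
        table = sub.pivot(index="year", columns="group", values="weighted_mean")
        table.columns = [f"group_{g}" for g in table.columns]
        table.to_csv(report_dir / f"group_{f}.csv", float_format="%.12g")

    ensemble_dir = artifact_dir / "ensemble"
    bands = {}
    if ensemble_dir.exists():
        for qf in sorted(ensemble_dir.glob("quantiles_*.csv")):
            bands[qf.stem.removeprefix("quantiles_")] = pd.read_csv(qf, index_col="year")
    else:
        notes.append("no ensemble directory; uncertainty bands omitted")

    if plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        forecast_start = proj.loc[proj["forecast"], "year"].min() if proj["forecast"].any() else None
        for _, f in REPORT_FIELDS:
            if f not in have_fields:
                continue
            sub = series[series["field"] == f]
            fig, ax = plt.subplots(figsize=(7, 4))
            for g, gdf in sub.groupby("group"):
                ax.plot(gdf["year"], gdf["weighted_mean"], label=f"Group {g}")
            if f in bands:
                b = bands[f]
                ax.fill_between(b.index, b["q25"], b["q75"], alpha=0.2, color="grey",
                                label="interquartile band (all countries)")
            if forecast_start is not None:
                ax.axvspan(sub["year"].min(), forecast_start, alpha=0.08, color="tab:blue")
            ax.set_xlabel("year")
            ax.set_ylabel(f.replace("_", " "))
            ax.legend(fontsize=8)
            fig.tight_layout()
            fig.savefig(report_dir / f"group_{f}.png", dpi=120)
            plt.close(fig)

    (report_dir / "NOTES.txt").write_text("\n".join(notes) + ("\n" if notes else ""))
    return report_dir
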