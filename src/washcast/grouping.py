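"""Trajectory-based country grouping and population-weighted aggregation.

Countries are classified into four WASH-mortality trajectory groups from two
numbers: the baseline mortality rate (last observed year) and the projected
base-case rate at a terminal year (default 2050), both in deaths per 1,000
per year:

* **Group 1** — high baseline (>= ``moderate_baseline``) that stays high
  (terminal >= ``terminal_high``): little progress by the horizon.
* **Group 2** — the residual class: moderate-to-high baseline with a steady
  but incomplete decline.
* **Group 3** — moderate baseline (in [``low_baseline``,
  ``moderate_baseline``)) declining to negligible levels (< ``negligible``).
* **Group 4** — low baseline (< ``low_baseline``) throughout.

The default thresholds (0.5 / 1.0 / 0.1 / 1.0) encode the narrative
definitions of the four trajectories; all are configurable because no formal
rule accompanies them. Classification uses the base-case trajectory, not
ensemble quantiles, and is total: every (baseline, terminal) pair maps to
exactly one group.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import pandas as pd

from .data_model import GroupAssignment, Panel
from .projection import ProjectionResult

__all__ = ["GroupThresholds", "classify_country", "classify_projection", "group_aggregate"]


@dataclass(frozen=True)
class GroupThresholds:
    low_baseline: float = 0.5
    moderate_baseline: float = 1.0
    negligible: float = 0.1
    terminal_high: float = 1.0
    terminal_year: int = 2050

    def __post_init__(self):
        if not self.negligible < self.low_baseline < self.moderate_baseline:
            raise ValueError("require negligible < low_baseline < moderate_baseline")
        if not self.terminal_high > self.negligible:
            raise ValueError("require terminal_high > negligible")


def classify_country(
    baseline_rate: float,
    terminal_rate: float,
    thresholds: GroupThresholds = GroupThresholds(),
) -> int:
    """Map (baseline, terminal) mortality rates to a trajectory group."""
    if baseline_rate < 0 or terminal_rate < 0:
        raise ValueError("mortality rates must be non-negative")
    t = thresholds
    if baseline_rate < t.low_baseline:
        return 4
    if t.low_baseline <= baseline_rate < t.moderate_baseline and terminal_rate < t.negligible:
        return 3
    if baseline_rate >= t.moderate_baseline and terminal_rate >= t.terminal_high:
        return 1
    return 2


def classify_projection(
    result: ProjectionResult,
    baseline: Panel,
    thresholds: GroupThresholds = GroupThresholds(),
) -> list[GroupAssignment]:
    """Classify every projected country.

    Baseline rate: the country's last observed panel rate. Terminal rate:
    the base-case projection at ``thresholds.terminal_year``.
    """
    base = baseline.latest_observed()
    terminal = result.at_year(thresholds.terminal_year)
    out = []
    for cid in sorted(result.frame["country_id"].unique()):
        if cid not in base.index:
            raise ValueError(f"country {cid!r} missing from baseline panel")
        if cid not in terminal.index:
            raise ValueError(
                f"country {cid!r} has no projection at terminal year {thresholds.terminal_year}"
            )
        b = float(base.loc[cid, "mortality_wash"])
        e = float(terminal.loc[cid, "mortality_wash"])
        out.append(
            GroupAssignment(
                country_id=cid,
                group=classify_country(b, e, thresholds),
                baseline_rate=b,
                terminal_rate=e,
                thresholds_used=asdict(thresholds),
            )
        )
    return out


#: fields aggregated by summation (counts and currency flows); everything
#: else is averaged with same-year population weights
EXTENSIVE_FIELDS = {
    "deaths", "population", "health_loss", "time_loss", "total_loss",
    "mortality_component", "morbidity_component",
}


def group_aggregate(
    frame: pd.DataFrame | ProjectionResult,
    assignments: list[GroupAssignment],
    field: str,
) -> pd.DataFrame:
    """Per-(group, year) aggregate of one output field.

    Returns a frame indexed by (group, year) with the population-weighted
    mean of ``field``, its group total (meaningful for extensive fields),
    and group population. Raises if any country lacks an assignment.
    """
    df = frame.frame if isinstance(frame, ProjectionResult) else frame
    group_of = {a.country_id: a.group for a in assignments}
    unassigned = sorted(set(df["country_id"].unique()) - set(group_of))
    if unassigned:
        raise ValueError(f"no group assignment for: {unassigned}")
    df = df.copy()
    df["group"] = df["country_id"].map(group_of)
    weighted = df[field] * df["population"]
    g = df.groupby(["group", "year"])
    out = pd.DataFrame(
        {
            "weighted_mean": weighted.groupby([df["group"], df["year"]]).sum()
            / g["population"].sum(),
            "total": g[field].sum(),
            "population": g["population"].sum(),
        }
    )
    out.index.names = ["group", "year"]
    return out
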