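#!/usr/bin/env python
"""Classify countries into the four mortality-trajectory groups.

Groups depend only on the baseline rate and the projected 2050 rate:
(1) high and staying high, (2) moderate with incomplete decline,
(3) moderate declining to negligible, (4) low throughout. Group series are
population-weighted means (rates, times) and totals (deaths, losses).
"""

from pathlib import Path

import pandas as pd

from washcast import (
    ProjectionResult,
    classify_projection,
    group_aggregate,
    read_panel,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    panel = read_panel(ROOT / "data" / "panel.csv")
    result = ProjectionResult(frame=pd.read_csv(ROOT / "projections.csv"))
    ledger = pd.read_csv(ROOT / "losses.csv")
    assignments = classify_projection(result, panel)

    groups = pd.DataFrame(
        [{"country_id": a.country_id, "group": a.group,
          "baseline_rate": a.baseline_rate, "terminal_rate": a.terminal_rate}
         for a in assignments]
    )
    groups.to_csv(ROOT / "groups.csv", index=False, float_format="%.12g")

    merged = result.frame.merge(
        ledger[["country_id", "year", "health_loss", "time_loss", "total_loss"]],
        on=["country_id", "year"],
    )
    series = []
    for field in ("mortality_wash", "deaths", "collection_time",
                  "health_loss", "time_loss", "total_loss"):
        agg = group_aggregate(merged, assignments, field).reset_index()
        agg.insert(0, "field", field)
        series.append(agg)
    pd.concat(series, ignore_index=True).to_csv(
        ROOT / "group_series.csv", index=False, float_format="%.12g"
    )

    counts = groups["group"].value_counts().sort_index()
    print("group sizes:", dict(counts))
    terminal = merged[merged["year"] == merged["year"].max()]
    gdeaths = terminal.merge(groups, on="country_id").groupby("group")["deaths"].sum()
    share = gdeaths / gdeaths.sum()
    print("share of terminal-year deaths by group:",
          {g: f"{s:.1%}" for g, s in share.items()})


if __name__ == "__main__":
    main()
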