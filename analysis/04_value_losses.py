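#!/usr/bin/env python
"""Value the projected health and time burdens.

Health losses use a VSL benefit transfer (reference 100x reference income,
unit income elasticity) with morbidity at 25% of mortality losses; time
losses value collection trips at half the bottom-80% per-capita income.
All figures in constant 1990 international dollars per year.
"""

from pathlib import Path

import pandas as pd

from washcast import ProjectionResult, ValuationConfig, compute_loss_ledger, read_panel

ROOT = Path(__file__).resolve().parents[1] / "results"

VALUATION = ValuationConfig(vsl_ref=100_000.0, y_ref=2_000.0)


def main() -> None:
    panel = read_panel(ROOT / "data" / "panel.csv")
    result = ProjectionResult(frame=pd.read_csv(ROOT / "projections.csv"))
    ledger = compute_loss_ledger(result, VALUATION, panel)
    ledger.frame.to_csv(ROOT / "losses.csv", index=False, float_format="%.12g")

    f = ledger.frame
    terminal = f[f["year"] == f["year"].max()]
    print(f"loss ledger: {len(f)} rows -> {ROOT / 'losses.csv'}")
    print(f"  {int(f['year'].max())} totals: health {terminal['health_loss'].sum():.3g}, "
          f"time {terminal['time_loss'].sum():.3g}, "
          f"total {terminal['total_loss'].sum():.3g} $/yr")
    share = terminal["time_loss"].sum() / terminal["total_loss"].sum()
    print(f"  time losses are {share:.1%} of terminal-year total losses")


if __name__ == "__main__":
    main()
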