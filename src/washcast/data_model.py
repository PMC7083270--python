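"""Domain types and panel I/O.

The package's central container is the country-year panel: one row per
(country, year) carrying the economy (per-capita GDP in 1990 international
dollars), demography (population, urban share, household size), water-access
coverage under the two nested definitions (any improved source, and its
piped-on-premises subset), the WASH-attributable mortality rate (deaths per
1,000 persons per year), the average one-way water-collection time (minutes),
a temperature path (deg C), the income share of the bottom 80 percent, and an
open-ended set of named control covariates.

Coverage is held internally as fractions in [0, 1]; mortality as deaths per
1,000 per year. CSV files may carry coverage in percent — the schema flag
converts at the boundary so no mixed-unit arithmetic happens inside the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CountryYearRecord",
    "Panel",
    "PanelSchema",
    "PanelValidationError",
    "GroupAssignment",
    "read_panel",
    "write_panel",
    "CONTROL_PREFIX",
    "CORE_COLUMNS",
]

CONTROL_PREFIX = "ctrl_"

#: canonical column order for panel CSV files
CORE_COLUMNS = [
    "country_id",
    "year",
    "gdp_pc",
    "population",
    "urban_share",
    "coverage_improved",
    "coverage_piped",
    "mortality_wash",
    "collection_time",
    "temperature",
    "income_share_b80",
    "household_size",
]

#: columns that must be in [0, 1]
_UNIT_INTERVAL = ["urban_share", "coverage_improved", "coverage_piped"]
#: columns that must be strictly positive
_POSITIVE = ["gdp_pc", "population", "household_size"]
#: columns that must be non-negative
_NONNEGATIVE = ["mortality_wash", "collection_time"]


class PanelValidationError(ValueError):
    """Raised when panel rows violate the domain invariants.

    ``problems`` lists ``(row_index, message)`` pairs, one per offending row,
    so callers can report every violation rather than the first.
    """

    def __init__(self, problems: list[tuple[int, str]]):
        self.problems = problems
        lines = [f"row {i}: {msg}" for i, msg in problems]
        super().__init__(
            f"{len(problems)} panel invariant violation(s):\n" + "\n".join(lines)
        )


@dataclass
class CountryYearRecord:
    """One country-year observation."""

    country_id: str
    year: int
    gdp_pc: float
    population: float
    urban_share: float
    coverage_improved: float
    coverage_piped: float
    mortality_wash: float
    collection_time: float
    temperature: float = 0.0
    income_share_b80: float = 0.5
    household_size: float = 5.0
    controls: dict[str, float] = field(default_factory=dict)


@dataclass
class GroupAssignment:
    """Trajectory-group label for one country.

    ``group`` is determined solely by the baseline and terminal mortality
    rates and the thresholds used (recorded for auditability).
    """

    country_id: str
    group: int
    baseline_rate: float
    terminal_rate: float
    thresholds_used: dict[str, float] = field(default_factory=dict)


@dataclass
class PanelSchema:
    """Maps canonical panel column names onto CSV column names.

    ``columns`` maps canonical name -> file column name; canonical names not
    listed are assumed to appear under their own name. ``coverage_in_percent``
    declares that the file carries coverage (and urban share) on the 0-100
    scale; values are divided by 100 on read and multiplied back on write.
    """

    columns: dict[str, str] = field(default_factory=dict)
    coverage_in_percent: bool = False

    def file_column(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


def _validate_frame(frame: pd.DataFrame) -> list[tuple[int, str]]:
    problems: list[tuple[int, str]] = []
    for col in _POSITIVE:
        bad = frame.index[frame[col].notna() & ~(frame[col] > 0)]
        problems += [(int(i), f"{col} must be > 0 (got {frame.at[i, col]!r})") for i in bad]
    for col in _NONNEGATIVE:
        bad = frame.index[frame[col].notna() & (frame[col] < 0)]
        problems += [(int(i), f"{col} must be >= 0 (got {frame.at[i, col]!r})") for i in bad]
    for col in _UNIT_INTERVAL:
        vals = frame[col]
        bad = frame.index[vals.notna() & ((vals < 0) | (vals > 1))]
        problems += [(int(i), f"{col} must lie in [0, 1] (got {frame.at[i, col]!r})") for i in bad]
    share = frame["income_share_b80"]
    bad = frame.index[share.notna() & ~((share > 0) & (share <= 1))]
    problems += [
        (int(i), f"income_share_b80 must lie in (0, 1] (got {frame.at[i, 'income_share_b80']!r})")
        for i in bad
    ]
    both = frame["coverage_piped"].notna() & frame["coverage_improved"].notna()
    nested = frame.index[both & (frame["coverage_piped"] > frame["coverage_improved"] + 1e-12)]
    problems += [
        (
            int(i),
            "coverage_piped exceeds coverage_improved "
            f"({frame.at[i, 'coverage_piped']!r} > {frame.at[i, 'coverage_improved']!r})",
        )
        for i in nested
    ]
    dup = frame.duplicated(subset=["country_id", "year"], keep=False)
    for i in frame.index[dup]:
        problems.append(
            (int(i), f"duplicate (country, year) = ({frame.at[i, 'country_id']}, {frame.at[i, 'year']})")
        )
    return sorted(set(problems))


class Panel:
    """A validated country-year panel.

    Wraps a :class:`pandas.DataFrame` with the canonical columns plus any
    number of ``ctrl_``-prefixed control covariates. Gaps in a country's year
    sequence are allowed; duplicate (country, year) pairs are not. Missing
    covariates are explicit NaN; estimation drops incomplete rows listwise.
    """

    def __init__(self, frame: pd.DataFrame, metadata: dict | None = None, validate: bool = True):
        missing = [c for c in CORE_COLUMNS if c not in frame.columns]
        if missing:
            raise PanelValidationError([(-1, f"missing mandatory column(s): {missing}")])
        ctrl_cols = sorted(c for c in frame.columns if c.startswith(CONTROL_PREFIX))
        frame = frame[CORE_COLUMNS + ctrl_cols].reset_index(drop=True)
        frame = frame.astype({"country_id": str, "year": int})
        if validate:
            problems = _validate_frame(frame)
            if problems:
                raise PanelValidationError(problems)
        self.frame = frame
        self.metadata = dict(metadata or {})

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[CountryYearRecord], metadata: dict | None = None) -> "Panel":
        rows = []
        for r in records:
            row = {c: getattr(r, c) for c in CORE_COLUMNS}
            row.update({CONTROL_PREFIX + k: v for k, v in r.controls.items()})
            rows.append(row)
        if not rows:
            frame = pd.DataFrame(columns=CORE_COLUMNS)
        else:
            frame = pd.DataFrame(rows)
        return cls(frame, metadata=metadata)

    # -- accessors --------------------------------------------------------
    @property
    def records(self) -> list[CountryYearRecord]:
        out = []
        ctrl_cols = self.control_columns
        for _, row in self.frame.iterrows():
            controls = {
                c[len(CONTROL_PREFIX):]: float(row[c])
                for c in ctrl_cols
                if not (isinstance(row[c], float) and math.isnan(row[c]))
            }
            out.append(
                CountryYearRecord(
                    **{c: row[c] for c in CORE_COLUMNS if c not in ("country_id", "year")},
                    country_id=str(row["country_id"]),
                    year=int(row["year"]),
                    controls=controls,
                )
            )
        return out

    @property
    def control_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c.startswith(CONTROL_PREFIX)]

    @property
    def countries(self) -> list[str]:
        return sorted(self.frame["country_id"].unique())

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Panel):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self.frame, other.frame, check_like=True)
            return True
        except AssertionError:
            return False

    def latest_observed(self) -> pd.DataFrame:
        """Last observed row per country (baseline for projections)."""
        idx = self.frame.groupby("country_id")["year"].idxmax()
        return self.frame.loc[idx].set_index("country_id")


def read_panel(path: str | Path, schema: PanelSchema | Mapping[str, str] | None = None) -> Panel:
    """Read a panel CSV, renaming and unit-converting per ``schema``.

    Raises :class:`PanelValidationError` if a mandatory column cannot be
    resolved or any row violates a domain invariant (all offending rows are
    reported with their index).
    """
    if schema is None:
        schema = PanelSchema()
    elif not isinstance(schema, PanelSchema):
        schema = PanelSchema(columns=dict(schema))
    raw = pd.read_csv(path)
    rename = {}
    missing = []
    for canonical in CORE_COLUMNS:
        col = schema.file_column(canonical)
        if col not in raw.columns:
            missing.append(col)
        else:
            rename[col] = canonical
    if missing:
        raise PanelValidationError([(-1, f"missing mandatory column(s): {missing}")])
    frame = raw.rename(columns=rename)
    if schema.coverage_in_percent:
        for col in _UNIT_INTERVAL:
            frame[col] = frame[col] / 100.0
    return Panel(frame, metadata={"source": str(path)})


def write_panel(panel: Panel, path: str | Path, schema: PanelSchema | None = None) -> None:
    """Write a panel to CSV with stable column order, controls flattened."""
    frame = panel.frame.copy()
    if schema is not None and schema.coverage_in_percent:
        for col in _UNIT_INTERVAL:
            frame[col] = frame[col] * 100.0
    cols = CORE_COLUMNS + sorted(c for c in frame.columns if c.startswith(CONTROL_PREFIX))
    frame = frame.reindex(columns=cols)
    # %.17g preserves doubles exactly across the round-trip
    frame.to_csv(path, index=False, float_format="%.17g")
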