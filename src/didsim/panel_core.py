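"""Balanced state-year panel: container, validation, and CSV I/O.

The panel is the basic data structure of the whole toolkit: one row per
(state, year) carrying a population denominator, a death count, the crude
death rate per 100,000 residents, and any number of time-varying covariates
(at minimum a state unemployment rate).  All downstream code (baseline
generation, effect injection, model fitting) operates on this container.

Years carry calendar labels but estimators use the internal panel index
t = 1..T obtained from :meth:`Panel.t_index`, which decouples model code
from the calendar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

PER_100K = 100_000.0

#: canonical column names; anything else in the frame is treated as a covariate
CORE_COLUMNS = ("state", "year", "population", "deaths", "crude_rate")

RATE_RTOL = 1e-9


class PanelSchemaError(ValueError):
    """A required column is missing or cannot be mapped."""


class PanelValidationError(ValueError):
    """The panel violates a structural invariant (carries the violation list)."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__(
            "invalid panel: " + "; ".join(self.violations[:10])
            + ("" if len(self.violations) <= 10 else f" (+{len(self.violations) - 10} more)")
        )


@dataclass
class Panel:
    """A balanced long-format state-year panel.

    ``data`` is sorted by (state, year) and contains the five core columns
    plus covariates.  Construct via :meth:`from_dataframe` so that missing
    rate/count columns are derived and ordering is normalised.
    """

    data: pd.DataFrame = field(repr=False)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, validate: bool = True) -> "Panel":
        df = df.copy()
        for col in ("state", "year", "population"):
            if col not in df.columns:
                raise PanelSchemaError(f"missing required column: {col!r}")
        if "deaths" not in df.columns and "crude_rate" not in df.columns:
            raise PanelSchemaError("need at least one of 'deaths' or 'crude_rate'")
        if "crude_rate" not in df.columns:
            df["crude_rate"] = df["deaths"] / df["population"] * PER_100K
        if "deaths" not in df.columns:
            df["deaths"] = np.rint(df["crude_rate"] * df["population"] / PER_100K).astype(np.int64)
        df["state"] = df["state"].astype(str)
        df["year"] = df["year"].astype(np.int64)
        df = df.sort_values(["state", "year"], kind="mergesort").reset_index(drop=True)
        # core columns first, covariates after, original covariate order kept
        cov = [c for c in df.columns if c not in CORE_COLUMNS]
        df = df[list(CORE_COLUMNS) + cov]
        panel = cls(data=df)
        if validate:
            violations = validate_panel(panel)
            if violations:
                raise PanelValidationError(violations)
        return panel

    # -- basic properties ----------------------------------------------------

    @property
    def states(self) -> list[str]:
        return sorted(self.data["state"].unique().tolist())

    @property
    def n_states(self) -> int:
        return self.data["state"].nunique()

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique().tolist())

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.data.columns if c not in CORE_COLUMNS]

    def t_index(self) -> pd.Series:
        """Internal time index t = 1..T aligned with ``data`` rows."""
        first = min(self.years)
        return self.data["year"] - first + 1

    def wide(self, column: str) -> pd.DataFrame:
        """Pivot one column to a states x years matrix (rows sorted)."""
        return self.data.pivot(index="state", columns="year", values=column).sort_index()

    def copy(self) -> "Panel":
        return Panel(data=self.data.copy())


# ---------------------------------------------------------------------------
# validation


def validate_panel(panel: Panel) -> list[str]:
    """Return a list of human-readable invariant violations (empty iff valid).

    Checks balance (one record per state-year, no year gaps), positivity of
    populations, integrality and non-negativity of deaths, and consistency of
    the crude rate with deaths/population at relative tolerance 1e-9.
    Violations are returned, never raised.
    """
    df = panel.data
    out: list[str] = []
    if len(df) == 0:
        return ["empty panel: no records"]

    states = panel.states
    years = panel.years
    # contiguous years
    if years != list(range(min(years), max(years) + 1)):
        missing_years = sorted(set(range(min(years), max(years) + 1)) - set(years))
        out.append(f"year gap: missing years {missing_years}")
    # balance
    counts = df.groupby(["state", "year"]).size()
    dup = counts[counts > 1]
    for (s, y), c in dup.items():
        out.append(f"duplicate record: state {s}, year {y} appears {c} times")
    expected = {(s, y) for s in states for y in years}
    present = set(map(tuple, df[["state", "year"]].itertuples(index=False)))
    for s, y in sorted(expected - present):
        out.append(f"unbalanced: missing (state {s}, year {y})")

    bad_pop = df[~(df["population"] > 0)]
    for r in bad_pop.itertuples():
        out.append(f"state {r.state}, year {r.year}: population must be > 0 (got {r.population})")
    deaths = df["deaths"].to_numpy()
    noninteger = df[np.abs(deaths - np.rint(deaths)) > 1e-9]
    for r in noninteger.itertuples():
        out.append(f"state {r.state}, year {r.year}: deaths not integer-valued ({r.deaths})")
    negative = df[df["deaths"] < 0]
    for r in negative.itertuples():
        out.append(f"state {r.state}, year {r.year}: deaths must be >= 0 ({r.deaths})")

    implied = df["deaths"] / df["population"] * PER_100K
    denom = np.maximum(np.abs(implied), 1e-300)
    rel = np.abs(df["crude_rate"] - implied) / denom
    # zero-death rows: require exact zero rate
    rel = np.where(implied == 0, np.abs(df["crude_rate"]), rel)
    mism = df[rel > RATE_RTOL]
    for r in mism.itertuples():
        imp = r.deaths / r.population * PER_100K
        out.append(
            f"state {r.state}, year {r.year}: rate mismatch "
            f"(crude_rate={r.crude_rate}, deaths/population*1e5={imp})"
        )
    return out


# ---------------------------------------------------------------------------
# I/O


def read_panel(path, schema: Mapping[str, str] | None = None) -> Panel:
    """Read a CSV state-year panel.

    ``schema`` maps file column names to canonical names, e.g.
    ``{"st": "state", "pop": "population"}``.  Requires state, year,
    population, and at least one of deaths / crude_rate; the missing one of
    the pair is derived (deaths rounded to the nearest integer).  Extra
    columns are preserved as covariates.
    """
    df = pd.read_csv(path)
    if schema:
        unknown = set(schema) - set(df.columns)
        if unknown:
            raise PanelSchemaError(f"schema refers to absent columns: {sorted(unknown)}")
        df = df.rename(columns=dict(schema))
    return Panel.from_dataframe(df)


def write_panel(panel: Panel, path) -> None:
    """Write the panel to CSV (UTF-8, header row, long format).

    Floats are written at full precision so that a read/write round trip is
    exact for integer fields and well within 1e-9 for real fields.
    """
    violations = validate_panel(panel)
    if violations:
        raise PanelValidationError(violations)
    panel.data.to_csv(path, index=False)
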