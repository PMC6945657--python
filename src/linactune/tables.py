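"""Bundled gamma-analysis tables from a published Varian Clinac 2100
beam-commissioning exercise (6 MV and 10 MV), exactly as printed.

Tables 1-4 and 8-11 are history sweeps (PDD and lateral-profile passing
rates vs number of histories) for the competing initial electron energies;
tables 5-7, 12, 14 and 15 are the serial-optimization stages (best-depth
1%/1mm rates per candidate value); table 13 is the cross-depth comparison
of the two leading energy-FWHM candidates at 10 MV.  These fixtures drive
the reproduction of the published decision outcomes without any
simulation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .tuning import (
    DepthComparison,
    StageResult,
    TrendRecord,
    build_trend,
    cross_depth_compare,
    stage_argmax,
)

__all__ = [
    "PublishedTable",
    "TABLE_IDS",
    "load_table",
    "trend_from_table",
    "stage_from_table",
    "depth_comparison_from_table",
]

TABLE_IDS = tuple(range(1, 16))

# (kind, nominal energy label, candidate energy MeV or stage parameter, scan kind)
_META = {
    1: ("sweep", "6MV", 6.26, "pdd"),
    2: ("sweep", "6MV", 5.40, "pdd"),
    3: ("sweep", "6MV", 6.26, "lateral"),
    4: ("sweep", "6MV", 5.40, "lateral"),
    5: ("stage", "6MV", "energy_fwhm", "lateral"),
    6: ("stage", "6MV", "focal_spot_fwhm", "lateral"),
    7: ("stage", "6MV", "divergence", "lateral"),
    8: ("sweep", "10MV", 10.7, "pdd"),
    9: ("sweep", "10MV", 10.5, "pdd"),
    10: ("sweep", "10MV", 10.7, "lateral"),
    11: ("sweep", "10MV", 10.5, "lateral"),
    12: ("stage", "10MV", "energy_fwhm", "lateral"),
    13: ("cross_depth", "10MV", "energy_fwhm", "lateral"),
    14: ("stage", "10MV", "focal_spot_fwhm", "lateral"),
    15: ("stage", "10MV", "divergence", "lateral"),
}

TABLE13_DEPTHS = (2.4, 5.0, 10.0, 20.0, 30.0)


@dataclass(frozen=True)
class PublishedTable:
    """One printed table: column names and numeric rows, verbatim."""

    table_id: int
    kind: str
    nominal: str
    subject: object  # candidate energy (sweep) or stage parameter name
    scan_kind: str
    columns: tuple
    rows: tuple

    def column(self, name: str) -> list:
        i = self.columns.index(name)
        return [row[i] for row in self.rows]


def load_table(table_id: int) -> PublishedTable:
    """Load a bundled table (1-15) with values exactly as printed."""
    if table_id not in _META:
        raise KeyError(f"unknown table id {table_id!r}; valid ids are 1..15")
    kind, nominal, subject, scan_kind = _META[table_id]
    path = resources.files("linactune") / "data" / "tables" / f"table{table_id:02d}.csv"
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        columns = tuple(next(reader))
        rows = tuple(tuple(float(x) for x in row) for row in reader if row)
    return PublishedTable(table_id, kind, nominal, subject, scan_kind, columns, rows)


def trend_from_table(table_id: int) -> TrendRecord:
    """Build a TrendRecord (with Pearson r) from a printed history sweep."""
    t = load_table(table_id)
    if t.kind != "sweep":
        raise ValueError(f"table {table_id} is not a history sweep")
    sweep = [
        (int(n * 1e6), unc, (r33, r22, r11))
        for n, unc, r33, r22, r11 in t.rows
    ]
    return build_trend(f"{t.subject:g} MeV", sweep, energy=t.subject)


def stage_from_table(table_id: int) -> StageResult:
    """Apply the stage argmax rule to a printed optimization-stage table.

    The printed per-candidate rate is already the best over scan depths,
    so each candidate contributes a single-depth rate list.
    """
    t = load_table(table_id)
    if t.kind != "stage":
        raise ValueError(f"table {table_id} is not an optimization stage")
    candidates = [row[0] for row in t.rows]
    per_depth = [[row[-1]] for row in t.rows]  # rate_1_1 column
    return stage_argmax(t.subject, candidates, per_depth)


def depth_comparison_from_table(table_id: int = 13) -> DepthComparison:
    """Cross-depth head-to-head of the two printed candidates (table 13)."""
    t = load_table(table_id)
    if t.kind != "cross_depth":
        raise ValueError(f"table {table_id} is not a cross-depth comparison")
    (a, b) = t.rows
    return cross_depth_compare(
        f"{t.subject}={a[0]:g}", a[2:],
        f"{t.subject}={b[0]:g}", b[2:],
        depths=TABLE13_DEPTHS,
    )
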