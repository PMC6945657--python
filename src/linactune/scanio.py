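"""Scan-file I/O and structured report serialization.

Scan curves travel in a minimal self-describing CSV dialect (a stand-in
for proprietary water-tank formats such as w2CAD/GBDS beam data files): a
commented header block followed by a two-column body.

    # linactune-scan 1
    # kind: lateral
    # depth_cm: 10.0
    # normalization: cax_100
    # spacing_cm: 0.2
    # units: cm,percent
    position_cm,dose_percent
    -8.0,0.31
    ...

``depth_cm`` appears for lateral profiles only.  Both LF and CRLF files
are accepted; malformed files are rejected with line-numbered messages.
Gamma reports serialize to JSON (full detail) and CSV (one row per
criteria set).
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .curves import ScanCurve

__all__ = ["read_scan", "write_scan", "ScanFormatError",
           "gamma_report_json", "gamma_report_csv", "trend_table_csv"]

FORMAT_MAGIC = "linactune-scan"
FORMAT_VERSION = "1"
_REQUIRED_KEYS = ("kind", "normalization", "spacing_cm")


class ScanFormatError(ValueError):
    """Malformed scan file; message carries the offending line number."""


def write_scan(path, curve: ScanCurve) -> None:
    """Write a curve in the scan CSV dialect (lossless round-trip)."""
    lines = [f"# {FORMAT_MAGIC} {FORMAT_VERSION}",
             f"# kind: {curve.kind}"]
    if curve.kind == "lateral":
        lines.append(f"# depth_cm: {float(curve.depth)!r}")
    lines += [f"# normalization: {curve.normalization}",
              f"# spacing_cm: {float(curve.spacing)!r}",
              "# units: cm,percent",
              "position_cm,dose_percent"]
    for p, v in zip(curve.positions, curve.values):
        lines.append(f"{float(p)!r},{float(v)!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_scan(path) -> ScanCurve:
    """Parse a scan file, validating header and body."""
    text = Path(path).read_text(encoding="utf-8")
    header: dict[str, str] = {}
    positions: list[float] = []
    values: list[float] = []
    saw_columns = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if lineno == 1:
                if not body.startswith(FORMAT_MAGIC):
                    raise ScanFormatError(
                        f"line 1: not a {FORMAT_MAGIC} file (got {body[:40]!r})"
                    )
                continue
            if ":" in body:
                key, _, val = body.partition(":")
                header[key.strip()] = val.strip()
            continue
        if not saw_columns:
            if line.replace(" ", "") != "position_cm,dose_percent":
                raise ScanFormatError(
                    f"line {lineno}: expected column header "
                    f"'position_cm,dose_percent', got {line!r}"
                )
            saw_columns = True
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ScanFormatError(f"line {lineno}: expected two columns, got {line!r}")
        try:
            p, v = float(parts[0]), float(parts[1])
        except ValueError:
            raise ScanFormatError(f"line {lineno}: non-numeric value in {line!r}") from None
        if math.isnan(p) or math.isnan(v):
            raise ScanFormatError(f"line {lineno}: NaN value")
        if positions and p <= positions[-1]:
            raise ScanFormatError(
                f"line {lineno}: positions must be strictly increasing "
                f"({p} after {positions[-1]})"
            )
        positions.append(p)
        values.append(v)

    missing = [k for k in _REQUIRED_KEYS if k not in header]
    if missing:
        raise ScanFormatError(f"missing header key(s): {', '.join(missing)}")
    if len(positions) < 2:
        raise ScanFormatError("scan body needs at least two points")

    kind = header["kind"]
    depth = float(header["depth_cm"]) if "depth_cm" in header else None
    if kind == "lateral" and depth is None:
        raise ScanFormatError("missing header key(s): depth_cm (lateral scan)")
    return ScanCurve(
        kind=kind,
        positions=np.asarray(positions),
        values=np.asarray(values),
        spacing=float(header["spacing_cm"]),
        normalization=header["normalization"],
        depth=depth,
    )


def gamma_report_json(path, results, metadata: dict | None = None,
                      include_gamma: bool = False) -> None:
    """Write gamma results (one or many) to a versioned JSON report."""
    if not isinstance(results, (list, tuple)):
        results = [results]
    doc = {
        "schema": "linactune-gamma-report/1",
        "metadata": metadata or {},
        "results": [r.to_dict(include_gamma=include_gamma) for r in results],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def gamma_report_csv(path, results) -> None:
    """Write one CSV row per criteria set: criteria, counts, passing rate."""
    if not isinstance(results, (list, tuple)):
        results = [results]
    lines = ["dose_pct,dta_mm,n_points,n_pass,n_uncovered,passing_rate"]
    for r in results:
        lines.append(
            f"{r.criteria.dose_pct:g},{r.criteria.dta_mm:g},"
            f"{r.n_points},{r.n_pass},{r.n_uncovered},{r.passing_rate:.1f}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def trend_table_csv(path, trends) -> None:
    """Write TrendRecords as CSV mirroring the published table layout."""
    lines = ["candidate,energy_mev,n_histories_1e6,avg_uncertainty_pct,"
             "rate_3_3,rate_2_2,rate_1_1,pearson_r"]
    for t in trends:
        for row in t.rows:
            lines.append(
                f"{t.candidate_label},{t.energy:g},{row.n_histories / 1e6:g},"
                f"{row.avg_uncertainty:.2f},{row.rate_3_3:.1f},"
                f"{row.rate_2_2:.1f},{row.rate_1_1:.1f},{t.pearson_r:.4f}"
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
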