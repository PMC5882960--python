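"""Read and write Tucson (RWL) decadal measurement files and tabular data.

The Tucson decadal layout stores one series as consecutive lines of
``<id, <=8 chars> <decade year> <up to 10 integer values>``, each line
covering the remainder of a calendar decade. Two precision dialects are in
common circulation and both are supported:

* 0.01 mm units with stop marker ``999``;
* 0.001 mm units with stop marker ``-9999``.

The stop marker terminates a series and is not a measurement. ``auto``
detection reads the marker that actually ends each series.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .series import IncrementSeries, MonthlySeries, SeriesCollection

__all__ = [
    "read_rwl",
    "write_rwl",
    "read_monthly_table",
    "write_chronology_table",
    "read_chronology_table",
]

_DIALECTS = {
    "precision_0.01mm": {"scale": 100.0, "stop": 999},
    "precision_0.001mm": {"scale": 1000.0, "stop": -9999},
}


class RwlFormatError(ValueError):
    """Malformed Tucson decadal content."""


def _parse_lines(text: str):
    """Yield (series_id, decade_year, values) per non-blank line."""
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip():
            continue
        ident = raw[:8].strip()
        rest = raw[8:].split()
        # tolerate ids written past col 8 when whitespace-delimited
        if not ident:
            parts = raw.split()
            ident, rest = parts[0], parts[1:]
        if len(rest) < 2:
            raise RwlFormatError(f"line {lineno}: expected a year and at least one value")
        try:
            year = int(rest[0])
            values = [int(v) for v in rest[1:]]
        except ValueError as exc:
            raise RwlFormatError(f"line {lineno}: non-integer field ({exc})") from None
        yield lineno, ident, year, values


def read_rwl(path: str | Path, dialect: str = "auto") -> SeriesCollection:
    """Read a Tucson decadal file into a collection of increment series.

    ``dialect`` is ``auto`` (detected from each series' stop marker),
    ``precision_0.01mm`` or ``precision_0.001mm``. Widths are returned in mm.
    """
    if dialect not in ("auto", *_DIALECTS):
        raise ValueError(f"unknown dialect {dialect!r}")
    text = Path(path).read_text()

    per_series: dict[str, list[tuple[int, list[int]]]] = {}
    order: list[str] = []
    closed: set[str] = set()
    for lineno, ident, year, values in _parse_lines(text):
        if ident in closed:
            raise RwlFormatError(
                f"line {lineno}: series {ident!r} appears again after its stop marker"
            )
        if ident not in per_series:
            per_series[ident] = []
            order.append(ident)
        chunks = per_series[ident]
        if chunks and year <= chunks[-1][0]:
            raise RwlFormatError(
                f"line {lineno}: non-monotone decade years for series {ident!r}"
            )
        chunks.append((year, values))
        if values and values[-1] in (999, -9999):
            closed.add(ident)

    out = []
    for ident in order:
        chunks = per_series[ident]
        raw: list[int] = []
        first_year = chunks[0][0]
        expect = first_year
        for year, values in chunks:
            if year != expect:
                raise RwlFormatError(
                    f"series {ident!r}: decade line starting {year} does not follow {expect - 1}"
                )
            raw.extend(values)
            expect = year + len(values)
        stop = raw[-1] if raw else None
        if dialect == "auto":
            if stop == 999:
                dia = "precision_0.01mm"
            elif stop == -9999:
                dia = "precision_0.001mm"
            else:
                warnings.warn(
                    f"series {ident!r} has no stop marker; assuming 0.01 mm units",
                    stacklevel=2,
                )
                dia = "precision_0.01mm"
        else:
            dia = dialect
        spec = _DIALECTS[dia]
        if stop == spec["stop"]:
            raw = raw[:-1]
        widths = np.asarray(raw, dtype=float) / spec["scale"]
        out.append(IncrementSeries(specimen_id=ident, first_year=first_year, widths=widths))
    return SeriesCollection(out)


def write_rwl(
    collection: SeriesCollection,
    path: str | Path,
    dialect: str = "precision_0.01mm",
) -> None:
    """Write a collection in Tucson decadal layout (inverse of read_rwl)."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    spec = _DIALECTS[dialect]
    lines = []
    for s in collection:
        if len(s.specimen_id) > 8:
            raise RwlFormatError(
                f"specimen id {s.specimen_id!r} exceeds 8 characters"
            )
        ints = np.rint(s.widths * spec["scale"]).astype(int)
        if np.any(ints >= 100000) or np.any(ints <= 0):
            raise RwlFormatError(
                f"series {s.specimen_id!r}: width out of range for {dialect}"
            )
        values = list(ints) + [spec["stop"]]
        year = s.first_year
        pos = 0
        while pos < len(values):
            take = 10 - (year % 10)
            chunk = values[pos : pos + take]
            fields = "".join(f"{v:6d}" for v in chunk)
            lines.append(f"{s.specimen_id:<8s}{year:4d}{fields}")
            pos += take
            year += take
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_monthly_table(path: str | Path, name: str = "", units: str = "") -> MonthlySeries:
    """Read a year,month,value CSV into a MonthlySeries.

    Months outside 1-12 and duplicate (year, month) rows are format errors;
    months absent inside the span become tracked gaps, never interpolated.
    """
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    missing = [c for c in ("year", "month", "value") if c not in cols]
    if missing:
        raise RwlFormatError(f"{path}: missing column(s) {missing}")
    return MonthlySeries.from_arrays(
        df[cols["year"]].to_numpy(int),
        df[cols["month"]].to_numpy(int),
        df[cols["value"]].to_numpy(float),
        name=name or str(Path(path).stem),
        units=units,
    )


def write_monthly_table(series: MonthlySeries, path: str | Path) -> None:
    frame = series.to_frame()
    frame = frame[frame["value"].notna()]
    frame.to_csv(path, index=False)


def write_chronology_table(chronology, path: str | Path, retained_only: bool = True) -> None:
    """Write year, index, sample_depth, running_eps rows for a chronology."""
    frame = chronology.to_frame(retained_only=retained_only)
    frame.to_csv(path, index=False, columns=["year", "index", "sample_depth", "running_eps"])


def read_chronology_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
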