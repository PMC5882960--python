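"""Core data containers: increment series, collections, monthly environmental series.

Increment widths are stored oldest→youngest with a calendar anchor on the
first measured increment, regardless of the direction in which they were
measured on the specimen. Monthly environmental data are stored on a
complete monthly grid over their span; gaps are NaN and are tracked, never
interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IncrementSeries",
    "DetrendedSeries",
    "SeriesCollection",
    "MonthlySeries",
]


@dataclass(frozen=True)
class IncrementSeries:
    """One specimen's dated annual growth-increment widths in mm.

    Parameters
    ----------
    specimen_id : str
        Identifier, at most 8 characters when written to RWL.
    first_year : int
        Calendar year of the first (oldest) measured increment.
    widths : ndarray
        Strictly positive, finite widths in mm, ordered oldest→youngest.
    """

    specimen_id: str
    first_year: int
    widths: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.widths, dtype=float)
        object.__setattr__(self, "widths", w)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("widths must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise ValueError(
                f"series {self.specimen_id!r}: widths must be positive and finite"
            )

    def __len__(self) -> int:
        return self.widths.size

    @property
    def last_year(self) -> int:
        return self.first_year + len(self) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.widths, index=self.years, name=self.specimen_id)


@dataclass(frozen=True)
class DetrendedSeries:
    """Dimensionless growth indices after removal of the ontogenetic curve.

    ``mode='ratio'`` indices are observed/fitted (unit mean, positive);
    ``mode='residual'`` indices are observed−fitted in (possibly
    power-transformed) measurement space, approximately zero mean.
    ``power_exponent`` records the adaptive power transform applied before
    detrending (1.0 means none, 0.0 means log).
    """

    specimen_id: str
    first_year: int
    indices: np.ndarray
    mode: str = "ratio"
    power_exponent: float = 1.0

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=float)
        object.__setattr__(self, "indices", idx)
        if self.mode not in ("ratio", "residual"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "ratio" and np.any(idx[np.isfinite(idx)] <= 0):
            raise ValueError("ratio indices must be positive")

    def __len__(self) -> int:
        return self.indices.size

    @property
    def last_year(self) -> int:
        return self.first_year + len(self) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.indices, index=self.years, name=self.specimen_id)


class SeriesCollection:
    """An ordered collection of increment (or detrended) series with unique ids."""

    def __init__(self, series: Iterable[IncrementSeries | DetrendedSeries]):
        self._series = list(series)
        ids = [s.specimen_id for s in self._series]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate specimen ids: {dupes}")

    def __iter__(self) -> Iterator:
        return iter(self._series)

    def __len__(self) -> int:
        return len(self._series)

    def __getitem__(self, key):
        if isinstance(key, str):
            for s in self._series:
                if s.specimen_id == key:
                    return s
            raise KeyError(key)
        return self._series[key]

    @property
    def ids(self) -> list[str]:
        return [s.specimen_id for s in self._series]

    @property
    def span(self) -> tuple[int, int]:
        """(earliest first_year, latest last_year) over all members."""
        if not self._series:
            raise ValueError("empty collection has no span")
        return (
            min(s.first_year for s in self._series),
            max(s.last_year for s in self._series),
        )

    def subset(self, ids: Sequence[str]) -> "SeriesCollection":
        wanted = set(ids)
        return SeriesCollection([s for s in self._series if s.specimen_id in wanted])

    def drop(self, specimen_id: str) -> "SeriesCollection":
        return SeriesCollection(
            [s for s in self._series if s.specimen_id != specimen_id]
        )

    def to_frame(self) -> pd.DataFrame:
        """Years × specimens matrix; NaN where a specimen has no increment."""
        if not self._series:
            return pd.DataFrame()
        return pd.concat([s.to_pandas() for s in self._series], axis=1).sort_index()

    def __eq__(self, other) -> bool:
        if not isinstance(other, SeriesCollection):
            return NotImplemented
        if self.ids != other.ids:
            return False
        for a, b in zip(self, other):
            if a.first_year != b.first_year:
                return False
            va = a.widths if hasattr(a, "widths") else a.indices
            vb = b.widths if hasattr(b, "widths") else b.indices
            if va.shape != vb.shape or not np.allclose(va, vb):
                return False
        return True


def _month_index(start: pd.Period, end: pd.Period) -> pd.PeriodIndex:
    return pd.period_range(start, end, freq="M")


@dataclass
class MonthlySeries:
    """A monthly environmental time series on a complete calendar grid.

    ``data`` is indexed by a monthly PeriodIndex covering the whole span;
    gap months are NaN and reported by :attr:`gaps`.
    """

    name: str
    data: pd.Series
    units: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.PeriodIndex) or self.data.index.freqstr not in ("M",):
            raise ValueError("MonthlySeries data must be indexed by a monthly PeriodIndex")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate (year, month) keys")
        full = _month_index(self.data.index.min(), self.data.index.max())
        self.data = self.data.reindex(full).astype(float)

    @classmethod
    def from_arrays(
        cls,
        years: Sequence[int],
        months: Sequence[int],
        values: Sequence[float],
        name: str = "",
        units: str = "",
    ) -> "MonthlySeries":
        years = np.asarray(years, dtype=int)
        months = np.asarray(months, dtype=int)
        if np.any((months < 1) | (months > 12)):
            bad = months[(months < 1) | (months > 12)]
            raise ValueError(f"month outside 1-12: {bad.tolist()}")
        idx = pd.PeriodIndex.from_fields(year=years, month=months, freq="M")
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique()
            raise ValueError(f"duplicate (year, month) keys: {list(map(str, dupes))}")
        return cls(name=name, data=pd.Series(np.asarray(values, float), index=idx))

    def value(self, year: int, month: int) -> float:
        return float(self.data[pd.Period(year=year, month=month, freq="M")])

    @property
    def span_years(self) -> tuple[int, int]:
        return int(self.data.index.min().year), int(self.data.index.max().year)

    @property
    def gaps(self) -> pd.PeriodIndex:
        return self.data.index[self.data.isna()]

    def __len__(self) -> int:
        return len(self.data)

    def with_data(self, data: pd.Series, name: str | None = None) -> "MonthlySeries":
        return MonthlySeries(name=self.name if name is None else name,
                             data=data, units=self.units)

    def to_frame(self) -> pd.DataFrame:
        idx = self.data.index
        return pd.DataFrame(
            {"year": idx.year, "month": idx.month, "value": self.data.to_numpy()}
        )
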