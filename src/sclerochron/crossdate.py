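"""Crossdating quality control on spline-ratio detrended series.

Each detrended series is compared against the leave-one-out arithmetic mean
of the others ("master"): whole-series interseries correlations summarize
crossdating quality, low-correlation segments are flagged for re-inspection,
and a lag search localizes probable insertion/omission dating errors.
Descriptive statistics (mean sensitivity, first-order autocorrelation,
segment length) accompany the report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .series import SeriesCollection

__all__ = [
    "QCReport",
    "SegmentFlag",
    "mean_sensitivity",
    "first_order_autocorrelation",
    "interseries_correlation",
    "best_lag",
    "segment_flags",
    "qc_report",
]

MIN_OVERLAP = 10  # years required for any correlation used in QC


@dataclass(frozen=True)
class SegmentFlag:
    specimen_id: str
    start_year: int
    end_year: int
    r: float
    p: float
    best_lag: int
    r_at_best_lag: float


@dataclass
class QCReport:
    """Per-series and overall crossdating statistics."""

    per_series: pd.DataFrame  # specimen_id, leave_one_out_r, mean_sensitivity, lag1_autocorr, n_years
    flags: list[SegmentFlag]
    series_intercorrelation: float
    average_mean_sensitivity: float
    mean_segment_length: float

    def to_frame(self) -> pd.DataFrame:
        return self.per_series.copy()

    def flags_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "specimen_id": f.specimen_id,
                    "start_year": f.start_year,
                    "end_year": f.end_year,
                    "r": f.r,
                    "p": f.p,
                    "best_lag": f.best_lag,
                    "r_at_best_lag": f.r_at_best_lag,
                }
                for f in self.flags
            ],
            columns=[
                "specimen_id",
                "start_year",
                "end_year",
                "r",
                "p",
                "best_lag",
                "r_at_best_lag",
            ],
        )


def mean_sensitivity(widths) -> float:
    """Mean absolute relative difference between successive increments.

    MS = (1/(n-1)) * sum |2 (x_{t+1}-x_t) / (x_{t+1}+x_t)|; bounded by 2 for
    nonnegative inputs and invariant to rescaling.
    """
    x = np.asarray(widths, dtype=float)
    if x.size < 2:
        raise ValueError("mean sensitivity needs >= 2 values")
    sums = x[1:] + x[:-1]
    if np.any(sums == 0):
        raise ValueError("adjacent pair summing to zero")
    return float(np.mean(np.abs(2.0 * np.diff(x) / sums)))


def first_order_autocorrelation(values) -> float:
    """Lag-1 sample autocorrelation, mean-centered with the biased (1/n) denominator."""
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise ValueError("lag-1 autocorrelation needs >= 10 values")
    x = x - x.mean()
    denom = np.dot(x, x)
    if denom == 0:
        raise ValueError("zero variance")
    return float(np.dot(x[:-1], x[1:]) / denom)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt(np.dot(a, a) * np.dot(b, b))
    if denom == 0:
        return np.nan
    return float(np.dot(a, b) / denom)


def _loo_masters(frame: pd.DataFrame) -> pd.DataFrame:
    """Leave-one-out arithmetic means, one column per series."""
    total = frame.sum(axis=1, min_count=1)
    count = frame.notna().sum(axis=1)
    masters = {}
    for col in frame.columns:
        have = frame[col].notna()
        n_other = count - have.astype(int)
        other_sum = total - frame[col].fillna(0.0)
        m = other_sum / n_other.replace(0, np.nan)
        masters[col] = m
    return pd.DataFrame(masters)


def interseries_correlation(
    detrended: SeriesCollection,
) -> tuple[float, pd.Series]:
    """Correlate each detrended series with the mean of all the others.

    Returns the overall value (mean of per-series correlations) and the
    per-series values. Series with fewer than 10 years of overlap with
    their leave-one-out master are reported NaN and excluded from the
    overall mean, with a warning.
    """
    if len(detrended) < 3:
        raise ValueError("interseries correlation needs >= 3 series")
    frame = detrended.to_frame()
    masters = _loo_masters(frame)
    rs = {}
    for col in frame.columns:
        both = frame[col].notna() & masters[col].notna()
        if both.sum() < MIN_OVERLAP:
            warnings.warn(
                f"series {col!r}: < {MIN_OVERLAP} yr overlap with master; excluded",
                stacklevel=2,
            )
            rs[col] = np.nan
            continue
        rs[col] = _pearson(
            frame.loc[both, col].to_numpy(), masters.loc[both, col].to_numpy()
        )
    per = pd.Series(rs, name="leave_one_out_r")
    return float(per.dropna().mean()), per


def best_lag(
    series: pd.Series,
    master: pd.Series,
    max_lag: int = 5,
) -> tuple[int, float]:
    """Lag in [-max_lag, max_lag] maximizing the series-vs-master correlation.

    Lag ``L`` aligns series year ``y+L`` with master year ``y``: a series
    dated one year too late (an increment was missed) peaks at +1, a series
    with a spurious extra increment peaks at -1. Ties prefer lag 0, then
    negative lags. Both inputs are year-indexed.
    """
    results = {}
    for lag in range(-max_lag, max_lag + 1):
        shifted = series.copy()
        shifted.index = shifted.index - lag
        both = pd.concat([shifted, master], axis=1, join="inner").dropna()
        if len(both) < MIN_OVERLAP:
            continue
        r = _pearson(both.iloc[:, 0].to_numpy(), both.iloc[:, 1].to_numpy())
        if np.isfinite(r):
            results[lag] = r
    if not results:
        raise ValueError("insufficient overlap at every tested lag")
    # ties: 0 first, then negative before positive, then small |lag|
    best = max(
        results,
        key=lambda L: (results[L], L == 0, -abs(L), -np.sign(L)),
    )
    return int(best), float(results[best])


def _segment_bounds(first: int, last: int, seg_len: int, step: int):
    """Segment (start, end) years; a short tail >= 15 yr is kept."""
    bounds = []
    start = first
    while start + seg_len - 1 <= last:
        bounds.append((start, start + seg_len - 1))
        start += step
    covered_to = bounds[-1][1] if bounds else first - 1
    if covered_to < last:
        tail_start = max(first, last - seg_len + 1) if not bounds else bounds[-1][0] + step
        if last - tail_start + 1 >= 15:
            bounds.append((tail_start, last))
    return bounds


def segment_flags(
    detrended: SeriesCollection,
    seg_len: int = 30,
    overlap: int = 15,
    alpha: float = 0.01,
    max_lag: int = 5,
) -> list[SegmentFlag]:
    """Flag low-correlation segments against the leave-one-out master.

    Series are cut into ``seg_len``-year segments advanced by
    ``seg_len - overlap`` years; a segment whose correlation with the
    master fails a one-tailed (r > 0) t-test at ``alpha`` is flagged, and
    the flag carries the lag that best re-aligns the segment.
    """
    if seg_len < 10:
        raise ValueError("seg_len must be >= 10")
    if not 0 <= overlap < seg_len:
        raise ValueError("overlap must satisfy 0 <= overlap < seg_len")
    frame = detrended.to_frame()
    masters = _loo_masters(frame)
    step = seg_len - overlap
    flags: list[SegmentFlag] = []
    for s in detrended:
        col = frame[s.specimen_id].dropna()
        master = masters[s.specimen_id].dropna()
        for start, end in _segment_bounds(int(col.index.min()), int(col.index.max()), seg_len, step):
            seg = col.loc[start:end]
            mseg = master.loc[start:end]
            both = pd.concat([seg, mseg], axis=1, join="inner").dropna()
            n = len(both)
            if n < MIN_OVERLAP:
                continue
            r = _pearson(both.iloc[:, 0].to_numpy(), both.iloc[:, 1].to_numpy())
            if not np.isfinite(r):
                continue
            # one-tailed test for positive association; dating errors erase it
            t = r * np.sqrt((n - 2) / max(1e-12, 1.0 - r * r))
            p = float(stats.t.sf(t, df=n - 2))
            if p > alpha:
                try:
                    lag, r_lag = best_lag(seg, master, max_lag=max_lag)
                except ValueError:
                    lag, r_lag = 0, np.nan
                flags.append(
                    SegmentFlag(
                        specimen_id=s.specimen_id,
                        start_year=start,
                        end_year=end,
                        r=r,
                        p=p,
                        best_lag=lag,
                        r_at_best_lag=r_lag,
                    )
                )
    return flags


def qc_report(
    raw: SeriesCollection,
    detrended: SeriesCollection,
    seg_len: int = 30,
    overlap: int = 15,
    alpha: float = 0.01,
) -> QCReport:
    """Full crossdating QC: interseries correlations, sensitivity, flags."""
    overall, per_r = interseries_correlation(detrended)
    rows = []
    for s in raw:
        rows.append(
            {
                "specimen_id": s.specimen_id,
                "leave_one_out_r": per_r.get(s.specimen_id, np.nan),
                "mean_sensitivity": mean_sensitivity(s.widths),
                "lag1_autocorr": first_order_autocorrelation(s.widths)
                if len(s) >= 10
                else np.nan,
                "n_years": len(s),
            }
        )
    per = pd.DataFrame(rows)
    flags = segment_flags(detrended, seg_len=seg_len, overlap=overlap, alpha=alpha)
    return QCReport(
        per_series=per,
        flags=flags,
        series_intercorrelation=overall,
        average_mean_sensitivity=float(per["mean_sensitivity"].mean()),
        mean_segment_length=float(per["n_years"].mean()),
    )
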