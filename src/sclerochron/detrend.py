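"""Ontogenetic detrending of growth-increment series.

Two standardization paths are provided, mirroring the two stages of a
classical increment-chronology workflow:

* the crossdating-QC path fits each series with a cubic smoothing spline
  whose stiffness is set by a 50% frequency cutoff (default 15 yr) and
  divides observed by fitted values, isolating high-frequency variability;
* the chronology path applies an adaptive power transform to stabilize the
  spread–level relation, then removes a negative-exponential age trend by
  subtraction in transformed space.

The spline stiffness convention: the penalized smoothing spline acts on a
unit-spaced series as a low-pass filter with interior amplitude response
``1 / (1 + lambda * g(omega))`` where ``g(omega) = 12 (1-cos omega)^2 /
(2 + cos omega)``. The cutoff wavelength is the period at which this
response equals one half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import curve_fit

from .series import DetrendedSeries, IncrementSeries

__all__ = [
    "DetrendCurve",
    "spline_frequency_response",
    "smoothing_spline_fit",
    "adaptive_power_transform",
    "fit_age_trend",
    "detrend_series",
    "spline_ratio_detrend",
    "chronology_detrend",
]


@dataclass(frozen=True)
class DetrendCurve:
    """A fitted expected-growth curve aligned year-by-year with its series."""

    method: str  # spline | negexp | linear | mean
    specimen_id: str
    first_year: int
    fitted_values: np.ndarray
    params: dict

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + self.fitted_values.size)


def _g(omega: np.ndarray | float) -> np.ndarray | float:
    # spectral shape of the second-difference roughness penalty (unit spacing)
    return (1.0 - np.cos(omega)) ** 2 / (2.0 + np.cos(omega))


def spline_lambda(cutoff_years: float) -> float:
    """Roughness penalty giving a 50% amplitude response at ``cutoff_years``."""
    if cutoff_years <= 0:
        raise ValueError("cutoff_years must be positive")
    omega = 2.0 * np.pi / cutoff_years
    return (2.0 + np.cos(omega)) / (12.0 * (1.0 - np.cos(omega)) ** 2)


def spline_frequency_response(cutoff_years: float, period_years: float) -> float:
    """Interior amplitude response of the cutoff-parameterized smoothing spline.

    Exactly 0.5 at ``period_years == cutoff_years`` and monotone
    nondecreasing in period: long wavelengths pass, short ones are damped.
    """
    if cutoff_years <= 0 or period_years <= 0:
        raise ValueError("cutoff_years and period_years must be positive")
    ratio = _g(2.0 * np.pi / period_years) / _g(2.0 * np.pi / cutoff_years)
    return float(1.0 / (1.0 + ratio))


def smoothing_spline_fit(
    series: IncrementSeries, cutoff_years: float = 15.0
) -> DetrendCurve:
    """Fit the cutoff-parameterized cubic smoothing spline to one series."""
    if len(series) < 5:
        raise ValueError(
            f"series {series.specimen_id!r}: need >= 5 increments for a spline fit"
        )
    lam = spline_lambda(cutoff_years)
    x = np.arange(len(series), dtype=float)
    fitted = make_smoothing_spline(x, series.widths, lam=lam)(x)
    return DetrendCurve(
        method="spline",
        specimen_id=series.specimen_id,
        first_year=series.first_year,
        fitted_values=fitted,
        params={"cutoff_years": float(cutoff_years), "lambda": float(lam)},
    )


def adaptive_power_transform(
    widths: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Stabilize the spread-vs-level relation of a positive series.

    The local spread |x_{t+1}-x_t| is regressed (log-log) on the local level
    (x_t+x_{t+1})/2; with slope b the optimal power is p = 1-b, clamped to
    [0, 1]. |p| < 0.05 selects the log transform (p -> 0). Returns the
    transformed series and the exponent actually applied (0.0 encodes log).
    """
    x = np.asarray(widths, dtype=float)
    if np.any(x <= 0):
        raise ValueError("power transform requires strictly positive widths")
    if x.size < 10:
        raise ValueError("need >= 10 values to estimate the power exponent")
    spread = np.abs(np.diff(x))
    level = (x[:-1] + x[1:]) / 2.0
    keep = spread > 0
    if keep.sum() < 3:
        warnings.warn(
            "degenerate spread-level regression; exponent defaults to 1",
            stacklevel=2,
        )
        return x.copy(), 1.0
    b = np.polyfit(np.log(level[keep]), np.log(spread[keep]), 1)[0]
    p = float(np.clip(1.0 - b, 0.0, 1.0))
    if abs(p) < 0.05:
        return np.log(x), 0.0
    return x**p, p


def _negexp(age: np.ndarray, a: float, b: float, k: float) -> np.ndarray:
    return a * np.exp(-b * age) + k


def _fit_age_trend_values(
    w: np.ndarray, require_positive: bool = True
) -> tuple[np.ndarray, str, dict]:
    """Fit w(age) = a·exp(−b·age) + k with fallbacks; see fit_age_trend."""
    if w.size < 5:
        raise ValueError("need >= 5 increments to fit an age trend")
    age = np.arange(w.size, dtype=float)

    fitted = None
    params: dict = {}
    method = "negexp"
    k_lo = 0.0 if require_positive else -np.inf
    try:
        span = max(w[0] - w[-1], w.std())
        p0 = (max(span, 1e-3), 0.05, max(w.min() * 0.9, 1e-3) if require_positive else w.min())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _negexp,
                age,
                w,
                p0=p0,
                bounds=([1e-12, 1e-9, k_lo], [np.inf, np.inf, np.inf]),
                maxfev=5000,
            )
        a, b, k = (float(v) for v in popt)
        cand = _negexp(age, a, b, k)
        ok = np.all(cand > 0) if require_positive else np.all(np.isfinite(cand))
        # reject a flat or effectively non-declining "exponential"
        if ok and cand[0] - cand[-1] > 0.01 * w.std():
            fitted = cand
            params = {"a": a, "b": b, "k": k}
    except RuntimeError:
        pass

    if fitted is None:
        slope, intercept = np.polyfit(age, w, 1)
        cand = slope * age + intercept
        pos_ok = np.all(cand > 0) if require_positive else True
        if slope <= 0 and pos_ok:
            fitted, method = cand, "linear"
            params = {"slope": float(slope), "intercept": float(intercept)}
        else:
            fitted, method = np.full_like(w, w.mean()), "mean"
            params = {"mean": float(w.mean())}
    return fitted, method, params


def fit_age_trend(series: IncrementSeries) -> DetrendCurve:
    """Fit a declining age trend w(age) = a·exp(−b·age) + k, a,b > 0, k ≥ 0.

    Falls back to a nonpositive-slope linear fit when the exponential does
    not converge or violates its constraints, and to the horizontal mean
    when even the linear slope is positive (juvenile-growth-still-rising
    series). The returned curve is strictly positive in all branches.
    """
    fitted, method, params = _fit_age_trend_values(series.widths, require_positive=True)
    return DetrendCurve(
        method=method,
        specimen_id=series.specimen_id,
        first_year=series.first_year,
        fitted_values=fitted,
        params=params,
    )


def detrend_series(
    series: IncrementSeries,
    curve: DetrendCurve,
    mode: str = "ratio",
    power_exponent: float = 1.0,
) -> DetrendedSeries:
    """Turn observed widths + fitted curve into dimensionless growth indices.

    ``observed`` and ``curve`` must share years. In ratio mode the index is
    observed/fitted; in residual mode observed−fitted (both evaluated in
    whatever space the inputs live in — callers applying a power transform
    pass the transformed observations and a curve fitted to them).
    """
    if mode not in ("ratio", "residual"):
        raise ValueError(f"unknown mode {mode!r}")
    if (
        curve.first_year != series.first_year
        or curve.fitted_values.size != len(series)
    ):
        raise ValueError(
            f"series {series.specimen_id!r}: curve years do not align with series years"
        )
    obs = series.widths
    fit = curve.fitted_values
    if mode == "ratio":
        if np.any(fit <= 0):
            raise ValueError("ratio detrending requires a strictly positive curve")
        idx = obs / fit
    else:
        idx = obs - fit
    return DetrendedSeries(
        specimen_id=series.specimen_id,
        first_year=series.first_year,
        indices=idx,
        mode=mode,
        power_exponent=power_exponent,
    )


def spline_ratio_detrend(collection, cutoff_years: float = 15.0):
    """QC-path standardization: spline fit + ratio, applied per series."""
    from .series import SeriesCollection

    out = []
    for s in collection:
        curve = smoothing_spline_fit(s, cutoff_years=cutoff_years)
        out.append(detrend_series(s, curve, mode="ratio"))
    return SeriesCollection(out)


def chronology_detrend(collection, mode: str = "residual"):
    """Chronology-path standardization: adaptive power transform, then
    negative-exponential (or fallback) age-trend removal in transformed space.

    The log branch of the transform can produce nonpositive values, so the
    age trend is fitted with its level offset unconstrained there and the
    default detrending mode is residual subtraction; ratio mode falls back
    to untransformed widths to keep the denominator positive.
    """
    from .series import SeriesCollection

    out = []
    for s in collection:
        transformed, p = adaptive_power_transform(s.widths)
        if mode == "ratio" and np.any(transformed <= 0):
            transformed, p = s.widths.copy(), 1.0
        all_pos = bool(np.all(transformed > 0))
        fitted, _, _ = _fit_age_trend_values(
            transformed, require_positive=(mode == "ratio") or all_pos
        )
        if mode == "ratio":
            idx = transformed / fitted
        else:
            idx = transformed - fitted
        out.append(
            DetrendedSeries(
                specimen_id=s.specimen_id,
                first_year=s.first_year,
                indices=idx,
                mode=mode,
                power_exponent=p,
            )
        )
    return SeriesCollection(out)
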