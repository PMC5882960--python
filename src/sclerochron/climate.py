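"""Climate-growth inference: deseasonalized anomalies, growth-year alignment,
monthly Spearman correlation tables, and stepwise regression with an AR(1)
prewhitened re-test.

Growth years follow the shell's biology: the increment labeled ``y`` forms
from October of calendar year ``y-1`` through September of ``y``. A
chronology is therefore correlated against 18 month columns per variable:
the six months preceding increment onset (prior-year April–September) and
the twelve months of the growth year itself (October–September).
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .series import MonthlySeries

__all__ = [
    "GROWTH_YEAR_COLUMNS",
    "SEASONAL_PRESETS",
    "deseasonalize",
    "adt_index",
    "align_to_growth_year",
    "spearman",
    "CorrelationTable",
    "monthly_correlation_table",
    "seasonal_mean",
    "StepwiseResult",
    "stepwise_forward",
    "prewhiten_ar1",
    "AnalysisReport",
    "analysis_report",
]

# prior-year Apr-Sep, then the Oct(y-1)-Sep(y) growth year
_PRIOR = ["pApr", "pMay", "pJun", "pJul", "pAug", "pSep"]
_GROWTH = ["Oct", "Nov", "Dec", "Jan", "Feb", "Mar", "Apr", "May", "Jun", "Jul", "Aug", "Sep"]
GROWTH_YEAR_COLUMNS: list[str] = _PRIOR + _GROWTH

# (column label) -> (calendar month, year offset relative to growth year y)
_COLUMN_CALENDAR: dict[str, tuple[int, int]] = {
    **{lab: (m, -1) for lab, m in zip(_PRIOR, range(4, 10))},
    **{lab: (m, -1) for lab, m in zip(["Oct", "Nov", "Dec"], (10, 11, 12))},
    **{lab: (m, 0) for lab, m in zip(_GROWTH[3:], range(1, 10))},
}

SEASONAL_PRESETS: dict[str, list[str]] = {
    "JJA": ["Jun", "Jul", "Aug"],
    "FebMar": ["Feb", "Mar"],
    "AprMay": ["Apr", "May"],
    "OctSep": list(_GROWTH),
}


def deseasonalize(series: MonthlySeries) -> MonthlySeries:
    """Remove the mean plus annual and semi-annual harmonics by least squares.

    Gap months are excluded from the fit and stay gaps in the output.
    """
    data = series.data
    ok = data.notna()
    if ok.sum() < 36:
        raise ValueError("deseasonalization needs >= 3 complete years of data")
    t = np.arange(len(data), dtype=float) + data.index[0].month - 1
    design = np.column_stack(
        [
            np.ones_like(t),
            np.sin(2 * np.pi * t / 12),
            np.cos(2 * np.pi * t / 12),
            np.sin(4 * np.pi * t / 12),
            np.cos(4 * np.pi * t / 12),
        ]
    )
    y = data.to_numpy()
    coef, *_ = np.linalg.lstsq(design[ok.to_numpy()], y[ok.to_numpy()], rcond=None)
    resid = y - design @ coef
    out = pd.Series(resid, index=data.index)
    out[~ok] = np.nan
    return series.with_data(out, name=f"{series.name}_anom" if series.name else "anom")


def adt_index(north_box: MonthlySeries, central_box: MonthlySeries) -> MonthlySeries:
    """North-minus-central dynamic-topography difference, month by month.

    Positive values indicate the cyclonic circulation regime (inflow of
    ultraoligotrophic Eastern Mediterranean water to the Adriatic).
    """
    if not north_box.data.index.equals(central_box.data.index):
        raise ValueError("ADT boxes must share the same monthly span")
    return MonthlySeries(
        name="ADT", data=north_box.data - central_box.data, units=north_box.units
    )


def align_to_growth_year(series: MonthlySeries) -> pd.DataFrame:
    """Arrange monthly anomalies into the 18-column growth-year matrix.

    Row ``y`` holds prior-year April–September and the October(y−1) to
    September(y) growth year; rows with any month missing are dropped with
    a warning.
    """
    data = series.data
    y0, y1 = series.span_years
    rows = {}
    dropped = []
    for gy in range(y0, y1 + 2):
        vals = {}
        complete = True
        for col in GROWTH_YEAR_COLUMNS:
            month, off = _COLUMN_CALENDAR[col]
            p = pd.Period(year=gy + off, month=month, freq="M")
            v = data[p] if p in data.index else np.nan
            if not np.isfinite(v):
                complete = False
                break
            vals[col] = v
        if complete:
            rows[gy] = vals
        elif y0 < gy <= y1:
            dropped.append(gy)
    if dropped:
        warnings.warn(
            f"{series.name or 'series'}: dropped incomplete growth years {dropped[:5]}"
            + ("..." if len(dropped) > 5 else ""),
            stacklevel=2,
        )
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=GROWTH_YEAR_COLUMNS)
    frame.index.name = "growth_year"
    return frame


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-tailed p-value.

    Mid-ranks handle ties; p comes from the t approximation with n−2
    degrees of freedom, except for n < 10 where an exact permutation null
    over all n! orderings is evaluated. Zero rank variance in either input
    gives (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 4:
        raise ValueError("Spearman needs >= 4 paired observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return (np.nan, np.nan)
    r = float(np.corrcoef(rx, ry)[0, 1])
    if n < 10:
        cx = rx - rx.mean()
        cy = ry - ry.mean()
        denom = np.sqrt(np.dot(cx, cx) * np.dot(cy, cy))
        perms = np.array(list(itertools.permutations(cy)))
        rp = perms @ cx / denom
        return r, float(np.mean(np.abs(rp) >= abs(r) - 1e-12))
    t = r * math.sqrt((n - 2) / max(1e-300, 1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(min(p, 1.0))


def _tier(p: float) -> str:
    if not np.isfinite(p):
        return "none"
    if p < 0.05:
        return "95%"
    if p < 0.10:
        return "90%"
    return "none"


@dataclass
class CorrelationTable:
    """Per (variable, month-column) Spearman r/p with 90/95% significance tiers."""

    table: pd.DataFrame  # variable, month, r, p, n, tier
    alpha_expected_false_positives: float

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def significant(self, tier: str = "95%") -> pd.DataFrame:
        keep = ("95%",) if tier == "95%" else ("95%", "90%")
        return self.table[self.table["tier"].isin(keep)]

    def plot(self, variable: str, ax=None):
        """Bar chart of monthly correlations for one variable, tier-colored."""
        import matplotlib.pyplot as plt

        sub = self.table[self.table["variable"] == variable].set_index("month")
        sub = sub.reindex(GROWTH_YEAR_COLUMNS)
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        colors = {"95%": "tab:red", "90%": "tab:blue", "none": "0.7"}
        ax.bar(
            range(len(sub)),
            sub["r"].to_numpy(),
            color=[colors[t] for t in sub["tier"].fillna("none")],
        )
        ax.set_xticks(range(len(sub)), sub.index, rotation=90, fontsize=7)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_ylabel("Spearman r")
        ax.set_title(variable)
        return ax


def monthly_correlation_table(
    chronology: pd.Series,
    frames: dict[str, pd.DataFrame],
    min_years: int = 20,
) -> CorrelationTable:
    """Spearman r/p of the chronology against every variable × month column.

    ``chronology`` is a year-indexed series (growth years); each frame is
    an 18-column growth-year matrix from :func:`align_to_growth_year`.
    Overlaps below ``min_years`` are computed anyway but flagged.
    """
    rows = []
    n_tests = 0
    for var, frame in frames.items():
        joined = frame.join(chronology.rename("_chron"), how="inner").dropna(
            subset=["_chron"]
        )
        for col in GROWTH_YEAR_COLUMNS:
            pair = joined[[col, "_chron"]].dropna()
            n = len(pair)
            if n < 5:
                rows.append((var, col, np.nan, np.nan, n, "none", True))
                continue
            if n < min_years:
                warnings.warn(
                    f"{var}/{col}: only {n} overlapping growth years", stacklevel=2
                )
            r, p = spearman(pair[col].to_numpy(), pair["_chron"].to_numpy())
            rows.append((var, col, r, p, n, _tier(p), n < min_years))
            n_tests += 1
    table = pd.DataFrame(
        rows, columns=["variable", "month", "r", "p", "n", "tier", "short_overlap"]
    )
    return CorrelationTable(
        table=table, alpha_expected_false_positives=0.05 * n_tests
    )


def seasonal_mean(frame: pd.DataFrame, months) -> pd.Series:
    """Row-wise mean over named month columns (or a named preset)."""
    if isinstance(months, str):
        if months not in SEASONAL_PRESETS:
            raise KeyError(f"unknown seasonal preset {months!r}")
        months = SEASONAL_PRESETS[months]
    months = list(months)
    if not months:
        raise ValueError("months must be nonempty")
    unknown = [m for m in months if m not in frame.columns]
    if unknown:
        raise KeyError(f"unknown month column(s) {unknown}")
    return frame[months].mean(axis=1)


@dataclass
class StepwiseResult:
    """Outcome of forward stepwise selection on ordinary least squares."""

    candidates: list[str]
    selected: list[str]
    entry_pvalues: dict[str, float]
    coefficients: dict[str, float]
    multiple_r: float
    signed_r: float  # sign of the (single) predictor's slope times multiple r
    model_p: float
    n: int
    partial_r: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "candidates": self.candidates,
            "selected": self.selected,
            "entry_pvalues": self.entry_pvalues,
            "coefficients": self.coefficients,
            "multiple_r": self.multiple_r,
            "signed_r": self.signed_r,
            "model_p": self.model_p,
            "n": self.n,
            "partial_r": self.partial_r,
        }


def stepwise_forward(
    response: pd.Series,
    candidates: dict[str, pd.Series],
    p_enter: float = 0.05,
) -> StepwiseResult:
    """Forward selection: repeatedly add the candidate with the smallest
    partial-F p-value while it stays below ``p_enter``.

    Collinear candidates (rank-deficient once added) are skipped with a
    warning. ``signed_r`` carries the slope sign when exactly one predictor
    is selected, mirroring the convention of quoting a signed correlation
    for a single-driver model.
    """
    import statsmodels.api as sm

    if len(candidates) < 1:
        raise ValueError("need at least one candidate")
    frame = pd.concat(
        {"__y": response, **{k: v for k, v in candidates.items()}}, axis=1
    ).dropna()
    n = len(frame)
    if n < 10:
        raise ValueError("need >= 10 complete observations")
    y = frame["__y"].to_numpy()
    names = list(candidates)
    selected: list[str] = []
    entry_p: dict[str, float] = {}
    while True:
        best_name, best_p = None, np.inf
        for name in names:
            if name in selected:
                continue
            X = frame[selected + [name]].to_numpy()
            Xc = sm.add_constant(X)
            if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
                warnings.warn(f"candidate {name!r} collinear with current model; skipped",
                              stacklevel=2)
                continue
            fit = sm.OLS(y, Xc).fit()
            p = float(fit.pvalues[-1])  # partial F == squared t for one added term
            if p < best_p:
                best_name, best_p = name, p
        if best_name is None or best_p >= p_enter:
            break
        selected.append(best_name)
        entry_p[best_name] = best_p

    if selected:
        X = sm.add_constant(frame[selected].to_numpy())
        fit = sm.OLS(y, X).fit()
        coefs = {nm: float(b) for nm, b in zip(selected, fit.params[1:])}
        mr = float(np.sqrt(max(fit.rsquared, 0.0)))
        signed = mr * float(np.sign(fit.params[1])) if len(selected) == 1 else mr
        model_p = float(fit.f_pvalue)
        # partial correlations of each selected predictor given the others
        partial = {}
        for nm in selected:
            others = [o for o in selected if o != nm]
            ry = _residualize(frame["__y"], frame[others])
            rx = _residualize(frame[nm], frame[others])
            partial[nm] = float(np.corrcoef(ry, rx)[0, 1])
    else:
        coefs, mr, signed, model_p, partial = {}, 0.0, 0.0, np.nan, {}
    return StepwiseResult(
        candidates=names,
        selected=selected,
        entry_pvalues=entry_p,
        coefficients=coefs,
        multiple_r=mr,
        signed_r=signed,
        model_p=model_p,
        n=n,
        partial_r=partial,
    )


def _residualize(y: pd.Series, X: pd.DataFrame) -> np.ndarray:
    yv = y.to_numpy(dtype=float)
    if X.shape[1] == 0:
        return yv - yv.mean()
    A = np.column_stack([np.ones(len(y)), X.to_numpy(dtype=float)])
    coef, *_ = np.linalg.lstsq(A, yv, rcond=None)
    return yv - A @ coef


def prewhiten_ar1(series: pd.Series | np.ndarray) -> pd.Series:
    """Remove first-order autocorrelation: r_t = x_t − φ̂·x_{t−1}, mean restored.

    φ̂ is the biased lag-1 sample autocorrelation, clipped into (−0.99, 0.99)
    with a warning if the estimate leaves the stationary range. Output has
    length n−1 and keeps the input's index tail when index-aware.
    """
    idx = series.index[1:] if isinstance(series, pd.Series) else None
    x = np.asarray(series, dtype=float)
    if x.size < 10:
        raise ValueError("prewhitening needs >= 10 values")
    xc = x - x.mean()
    denom = np.dot(xc, xc)
    if denom == 0:
        raise ValueError("zero variance")
    phi = float(np.dot(xc[:-1], xc[1:]) / denom)
    if abs(phi) >= 1.0:
        warnings.warn(f"AR(1) estimate {phi:.3f} outside (-1,1); clipped", stacklevel=2)
        phi = math.copysign(0.99, phi)
    resid = x[1:] - phi * x[:-1]
    resid = resid - resid.mean() + x.mean()
    return pd.Series(resid, index=idx) if idx is not None else pd.Series(resid)


@dataclass
class AnalysisReport:
    """End-to-end climate-growth inference outputs."""

    correlations: CorrelationTable
    seasonal: pd.DataFrame  # growth-year rows x named seasonal predictors
    stepwise: StepwiseResult
    stepwise_prewhitened: StepwiseResult | None
    overlap_years: dict[str, int]

    def to_json(self, path=None) -> str:
        payload = {
            "stepwise": self.stepwise.to_dict(),
            "stepwise_prewhitened": (
                self.stepwise_prewhitened.to_dict()
                if self.stepwise_prewhitened is not None
                else None
            ),
            "overlap_years": self.overlap_years,
            "expected_false_positives": self.correlations.alpha_expected_false_positives,
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def analysis_report(
    chronology: pd.Series,
    variables: dict[str, MonthlySeries],
    seasonal_plan: dict[str, tuple[str, str]] | None = None,
    p_enter: float = 0.05,
    prewhiten: bool = True,
    already_deseasonalized: bool = False,
) -> AnalysisReport:
    """Run the full inference stage on a chronology and monthly variables.

    ``seasonal_plan`` maps predictor names to (variable, preset) pairs used
    as stepwise candidates, e.g. ``{"SST_JJA": ("SST", "JJA")}``; by default
    every variable contributes its October–September annual mean.
    """
    anomalies = {
        name: (var if already_deseasonalized else deseasonalize(var))
        for name, var in variables.items()
    }
    frames = {name: align_to_growth_year(a) for name, a in anomalies.items()}
    corr = monthly_correlation_table(chronology, frames)
    if seasonal_plan is None:
        seasonal_plan = {f"{name}_OctSep": (name, "OctSep") for name in frames}
    seasonal = pd.DataFrame(
        {
            pred: seasonal_mean(frames[var], preset)
            for pred, (var, preset) in seasonal_plan.items()
        }
    )
    candidates = {c: seasonal[c] for c in seasonal.columns}
    step = stepwise_forward(chronology, candidates, p_enter=p_enter)
    pw = None
    if prewhiten:
        joined = pd.concat({"__y": chronology, **candidates}, axis=1).dropna()
        pw_resp = prewhiten_ar1(joined["__y"])
        pw_cands = {c: prewhiten_ar1(joined[c]) for c in seasonal.columns}
        pw = stepwise_forward(pw_resp, pw_cands, p_enter=p_enter)
    overlap = {
        name: int(frame.join(chronology.rename("_c"), how="inner").dropna().shape[0])
        for name, frame in frames.items()
    }
    return AnalysisReport(
        correlations=corr,
        seasonal=seasonal,
        stepwise=step,
        stepwise_prewhitened=pw,
        overlap_years=overlap,
    )
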