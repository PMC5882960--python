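"""High-level modelling interface: build a chronology, then infer its
climate drivers.

`ChronologyModel` wraps the standardization → QC → averaging → signal
strength → truncation pipeline; `ClimateGrowthModel` wraps the
deseasonalization → growth-year alignment → Spearman screening → stepwise
regression (raw and prewhitened) stage. Both follow the familiar
model.fit() → results pattern with a text `summary()`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import chronology as chron_mod
from . import climate as climate_mod
from . import crossdate as qc_mod
from . import detrend as detrend_mod
from .series import MonthlySeries, SeriesCollection

__all__ = [
    "ChronologyModel",
    "ChronologyResult",
    "ClimateGrowthModel",
    "ClimateGrowthResult",
]


class ChronologyModel:
    """Growth-increment chronology estimator for a collection of shells.

    Parameters
    ----------
    collection : SeriesCollection
        Dated increment-width series (mm).
    spline_cutoff : float
        50% frequency cutoff (yr) for the QC spline detrending.
    detrend_mode : str
        'residual' (power transform + negative exponential, subtraction in
        transformed space) or 'ratio' for the chronology path.
    averaging : str
        'biweight' (robust, default) or 'mean'.
    """

    def __init__(
        self,
        collection: SeriesCollection,
        spline_cutoff: float = 15.0,
        detrend_mode: str = "residual",
        averaging: str = "biweight",
        window: int = 30,
        overlap: int = 29,
        min_depth: int = 10,
        eps_threshold: float = 0.85,
    ):
        self.collection = collection
        self.spline_cutoff = spline_cutoff
        self.detrend_mode = detrend_mode
        self.averaging = averaging
        self.window = window
        self.overlap = overlap
        self.min_depth = min_depth
        self.eps_threshold = eps_threshold

    @classmethod
    def from_rwl(cls, path, dialect: str = "auto", **kwargs) -> "ChronologyModel":
        from .rwl import read_rwl

        return cls(read_rwl(path, dialect=dialect), **kwargs)

    def fit(self) -> "ChronologyResult":
        qc_detrended = detrend_mod.spline_ratio_detrend(
            self.collection, cutoff_years=self.spline_cutoff
        )
        report = qc_mod.qc_report(self.collection, qc_detrended)
        detrended = detrend_mod.chronology_detrend(
            self.collection, mode=self.detrend_mode
        )
        chron = chron_mod.build_chronology(detrended, averaging=self.averaging)
        chron.running = chron_mod.running_eps(
            detrended, window=self.window, overlap=self.overlap
        )
        chron = chron_mod.truncate_chronology(
            chron, min_depth=self.min_depth, eps_threshold=self.eps_threshold
        )
        return ChronologyResult(model=self, qc=report, chronology=chron,
                                detrended=detrended, qc_detrended=qc_detrended)


@dataclass
class ChronologyResult:
    """Fitted chronology plus crossdating QC diagnostics."""

    model: ChronologyModel
    qc: qc_mod.QCReport
    chronology: chron_mod.Chronology
    detrended: SeriesCollection
    qc_detrended: SeriesCollection

    @property
    def series(self) -> pd.Series:
        """Retained (statistically robust) chronology, year-indexed."""
        return self.chronology.retained

    def summary(self) -> str:
        c = self.chronology
        lines = [
            "Growth-increment chronology",
            "=" * 43,
            f"series:                    {len(self.model.collection):>8d}",
            f"span:                      {c.years[0]}-{c.years[-1]}",
            f"mean segment length:       {self.qc.mean_segment_length:8.1f} yr",
            f"series intercorrelation:   {self.qc.series_intercorrelation:8.3f}",
            f"average mean sensitivity:  {self.qc.average_mean_sensitivity:8.3f}",
            f"rbar (pairwise):           {c.rbar:8.3f}",
            f"EPS (whole period):        {c.eps_overall:8.3f}",
            f"truncation year:           {c.truncation_year!s:>8s}",
            f"flagged segments:          {len(self.qc.flags):>8d}",
            f"averaging:                 {c.averaging:>8s}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        return self.chronology.plot(ax=ax)


class ClimateGrowthModel:
    """Climate-growth inference for a fitted (or supplied) chronology.

    Parameters
    ----------
    chronology : pd.Series | ChronologyResult
        Year-indexed growth index (growth years, Oct–Sep convention).
    variables : dict[str, MonthlySeries]
        Named monthly environmental series (raw; deseasonalized internally).
    seasonal_plan : dict[str, (variable, preset)] | None
        Stepwise candidate definitions, e.g. {"SST_JJA": ("SST", "JJA")}.
    """

    def __init__(
        self,
        chronology,
        variables: dict[str, MonthlySeries],
        seasonal_plan: dict[str, tuple[str, str]] | None = None,
        p_enter: float = 0.05,
        already_deseasonalized: bool = False,
    ):
        if isinstance(chronology, ChronologyResult):
            chronology = chronology.series
        self.chronology = chronology
        self.variables = variables
        self.seasonal_plan = seasonal_plan
        self.p_enter = p_enter
        self.already_deseasonalized = already_deseasonalized

    def fit(self, prewhiten: bool = True) -> "ClimateGrowthResult":
        report = climate_mod.analysis_report(
            self.chronology,
            self.variables,
            seasonal_plan=self.seasonal_plan,
            p_enter=self.p_enter,
            prewhiten=prewhiten,
            already_deseasonalized=self.already_deseasonalized,
        )
        return ClimateGrowthResult(model=self, report=report)


@dataclass
class ClimateGrowthResult:
    model: ClimateGrowthModel
    report: climate_mod.AnalysisReport

    @property
    def correlation_table(self) -> pd.DataFrame:
        return self.report.correlations.to_frame()

    @property
    def stepwise(self) -> climate_mod.StepwiseResult:
        return self.report.stepwise

    @property
    def stepwise_prewhitened(self) -> climate_mod.StepwiseResult | None:
        return self.report.stepwise_prewhitened

    def summary(self) -> str:
        sig = self.report.correlations.significant("90%")
        lines = [
            "Climate-growth analysis",
            "=" * 43,
            f"variables: {', '.join(sorted(self.report.overlap_years))}",
            f"overlap (growth years): {self.report.overlap_years}",
            "",
            "significant monthly correlations (90%+):",
        ]
        if len(sig):
            for _, row in sig.iterrows():
                lines.append(
                    f"  {row['variable']:>8s} {row['month']:>5s}  "
                    f"r={row['r']:+.2f} p={row['p']:.3f} ({row['tier']})"
                )
        else:
            lines.append("  none")
        lines.append(
            f"(~{self.report.correlations.alpha_expected_false_positives:.1f} "
            "false positives expected at 95% across the grid)"
        )
        for label, st in (
            ("stepwise (raw)", self.report.stepwise),
            ("stepwise (prewhitened)", self.report.stepwise_prewhitened),
        ):
            if st is None:
                continue
            lines += ["", f"{label}: n={st.n}"]
            if st.selected:
                for nm in st.selected:
                    lines.append(
                        f"  {nm}: coef={st.coefficients[nm]:+.3f} "
                        f"entry p={st.entry_pvalues[nm]:.4f} "
                        f"partial r={st.partial_r.get(nm, float('nan')):+.3f}"
                    )
                lines.append(
                    f"  multiple r={st.multiple_r:.3f} "
                    f"(signed {st.signed_r:+.3f}), model p={st.model_p:.4f}"
                )
            else:
                lines.append("  no predictor entered")
        return "\n".join(lines)

    def plot_correlations(self, variable: str, ax=None):
        return self.report.correlations.plot(variable, ax=ax)
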