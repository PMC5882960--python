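"""Deseasonalization, growth-year alignment, Spearman tables, stepwise."""

import json
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sclerochron as sc
from sclerochron.climate import (
    GROWTH_YEAR_COLUMNS,
    adt_index,
    align_to_growth_year,
    analysis_report,
    deseasonalize,
    monthly_correlation_table,
    prewhiten_ar1,
    seasonal_mean,
    spearman,
    stepwise_forward,
)


def monthly(values, start_year=1980, name="V"):
    n = len(values)
    years = start_year + np.arange(n) // 12
    months = np.arange(n) % 12 + 1
    return sc.MonthlySeries.from_arrays(years, months, values, name=name)


class TestDeseasonalize:
    @pytest.mark.parametrize("period", [12, 6])
    def test_pure_harmonic_removed(self, period):
        t = np.arange(120)
        ms = monthly(5 + 2 * np.sin(2 * np.pi * t / period + 0.3))
        resid = deseasonalize(ms).data.to_numpy()
        assert np.max(np.abs(resid)) < 1e-6

    def test_white_noise_variance_nearly_preserved(self):
        """Only ~5/n degrees of freedom are absorbed by the harmonic fit."""
        ratios = []
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=1200)
            resid = deseasonalize(monthly(x)).data.to_numpy()
            ratios.append(resid.var() / x.var())
        assert np.median(ratios) == pytest.approx(1.0, abs=0.02)

    def test_gaps_stay_gaps(self):
        t = np.arange(60, dtype=float)
        vals = 5 + 2 * np.sin(2 * np.pi * t / 12)
        vals[17] = np.nan
        ms = monthly(vals)
        out = deseasonalize(ms)
        assert len(out.gaps) == 1 and out.gaps[0] == ms.gaps[0]

    def test_requires_three_years(self):
        with pytest.raises(ValueError, match="3 complete years"):
            deseasonalize(monthly(np.ones(30)))


class TestAdtIndex:
    def test_constant_difference(self):
        n = monthly(np.full(48, 0.10), name="north")
        c = monthly(np.full(48, 0.04), name="central")
        np.testing.assert_allclose(adt_index(n, c).data.to_numpy(), 0.06)

    def test_identical_boxes_give_zero_and_antisymmetry(self):
        rng = np.random.default_rng(1)
        a = monthly(rng.normal(size=48))
        b = monthly(rng.normal(size=48))
        np.testing.assert_allclose(adt_index(a, a).data.to_numpy(), 0.0)
        np.testing.assert_allclose(
            adt_index(a, b).data.to_numpy(), -adt_index(b, a).data.to_numpy()
        )

    def test_span_mismatch_rejected(self):
        a = monthly(np.ones(48))
        b = monthly(np.ones(48), start_year=1990)
        with pytest.raises(ValueError, match="span"):
            adt_index(a, b)

    def test_commutes_with_deseasonalization(self):
        """Difference-then-deseasonalize equals deseasonalize-then-difference."""
        rng = np.random.default_rng(2)
        t = np.arange(240)
        north = monthly(10 + 3 * np.sin(2 * np.pi * t / 12) + rng.normal(size=240))
        central = monthly(9 + 2 * np.sin(2 * np.pi * t / 12) + rng.normal(size=240))
        one = deseasonalize(adt_index(north, central)).data.to_numpy()
        two = adt_index(deseasonalize(north), deseasonalize(central)).data.to_numpy()
        np.testing.assert_allclose(one, two, atol=1e-10)


class TestGrowthYearAlignment:
    def test_calendar_bookkeeping(self):
        ms = monthly(
            [100 * y + m for y in range(2010, 2017) for m in range(1, 13)],
            start_year=2010,
        )
        frame = align_to_growth_year(ms)
        assert list(frame.columns) == GROWTH_YEAR_COLUMNS
        row = frame.loc[2015]
        assert row["Oct"] == 201410  # growth year 2015 starts Oct 2014
        assert row["Sep"] == 201509
        assert row["pApr"] == 201404  # prior-year April
        assert row["Jan"] == 201501

    def test_first_complete_row_needs_prior_year(self):
        ms = monthly(np.arange(60, dtype=float), start_year=1980)
        frame = align_to_growth_year(ms)
        assert frame.index.min() == 1981


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(20, dtype=float)
        r, p = spearman(x, x**3)
        assert r == pytest.approx(1.0) and p < 1e-6
        r2, _ = spearman(x, -np.exp(x / 5))
        assert r2 == pytest.approx(-1.0)

    def test_hand_computed_midranks(self):
        r, p = spearman([1, 2, 2, 4], [1, 3, 2, 4])
        assert r == pytest.approx(4.5 / np.sqrt(22.5), abs=1e-6)
        assert 0 < p <= 1

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r0, p0 = spearman(x, y)
        r1, p1 = spearman(np.exp(x), y)
        r2, p2 = spearman(x, y**3)
        assert r0 == pytest.approx(r1) == pytest.approx(r2)
        assert p0 == pytest.approx(p1) == pytest.approx(p2)

    def test_matches_scipy_for_moderate_n(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=40), rng.normal(size=40)
        r, p = spearman(x, y)
        r_ref, p_ref = stats.spearmanr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_exact_permutation_small_n(self):
        # perfectly concordant n=6: exact two-tailed p = 2/6!
        x = np.arange(6, dtype=float)
        r, p = spearman(x, x + 0.5)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(2 / 720)

    def test_zero_rank_variance_undefined(self):
        r, p = spearman(np.ones(12), np.arange(12))
        assert np.isnan(r) and np.isnan(p)


@pytest.fixture(scope="module")
def driver_frame():
    drv = sc.simulate_environment_monthly(1970, 2016, seed=9)
    return align_to_growth_year(deseasonalize(drv))


class TestCorrelationTable:

    def test_self_column_is_perfect(self, driver_frame):
        chron = driver_frame["Feb"].rename("chron")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab = monthly_correlation_table(chron, {"DRV": driver_frame}).table
        cell = tab[(tab["variable"] == "DRV") & (tab["month"] == "Feb")].iloc[0]
        assert cell["r"] == pytest.approx(1.0) and cell["tier"] == "95%"

    def test_tiers_consistent_with_p_everywhere(self, driver_frame):
        rng = np.random.default_rng(5)
        chron = pd.Series(rng.normal(size=len(driver_frame)), index=driver_frame.index)
        tab = monthly_correlation_table(chron, {"DRV": driver_frame}).table
        for _, row in tab.dropna(subset=["p"]).iterrows():
            if row["p"] < 0.05:
                assert row["tier"] == "95%"
            elif row["p"] < 0.10:
                assert row["tier"] == "90%"
            else:
                assert row["tier"] == "none"

    def test_null_false_positive_rate(self, driver_frame):
        """A chronology independent of the climate grid triggers the 95% tier
        at roughly the nominal alpha across the 18 month columns."""
        fracs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            chron = pd.Series(
                rng.normal(size=len(driver_frame)), index=driver_frame.index
            )
            tab = monthly_correlation_table(chron, {"DRV": driver_frame}).table
            fracs.append((tab["tier"] == "95%").mean())
        assert np.mean(fracs) <= 0.08

    def test_expected_false_positive_count_reported(self, driver_frame):
        chron = driver_frame["Feb"].rename("chron")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ct = monthly_correlation_table(chron, {"A": driver_frame, "B": driver_frame})
        assert ct.alpha_expected_false_positives == pytest.approx(0.05 * 36)


class TestSeasonalMean:
    @pytest.fixture
    def frame(self):
        rng = np.random.default_rng(6)
        return pd.DataFrame(
            rng.normal(size=(10, 18)), columns=GROWTH_YEAR_COLUMNS, index=range(2000, 2010)
        )

    def test_presets(self, frame):
        np.testing.assert_allclose(
            seasonal_mean(frame, "JJA"), frame[["Jun", "Jul", "Aug"]].mean(axis=1)
        )
        np.testing.assert_allclose(
            seasonal_mean(frame, "OctSep"),
            frame[GROWTH_YEAR_COLUMNS[6:]].mean(axis=1),
        )

    def test_all_columns_equals_row_mean(self, frame):
        np.testing.assert_allclose(
            seasonal_mean(frame, GROWTH_YEAR_COLUMNS), frame.mean(axis=1)
        )

    def test_single_column_identity(self, frame):
        np.testing.assert_allclose(seasonal_mean(frame, ["Feb"]), frame["Feb"])

    def test_constant_frame(self, frame):
        const = frame * 0 + 3.0
        np.testing.assert_allclose(seasonal_mean(const, "FebMar"), 3.0)

    def test_unknown_column_rejected(self, frame):
        with pytest.raises(KeyError):
            seasonal_mean(frame, ["Smarch"])
        with pytest.raises(KeyError):
            seasonal_mean(frame, "NotAPreset")
        with pytest.raises(ValueError):
            seasonal_mean(frame, [])


class TestStepwise:
    def test_identical_candidate_selected_with_unit_r(self):
        rng = np.random.default_rng(7)
        y = pd.Series(rng.normal(size=30), index=range(1980, 2010))
        cands = {"SELF": y.copy(), "NOISE": pd.Series(rng.normal(size=30), index=y.index)}
        res = stepwise_forward(y, cands)
        assert res.selected[0] == "SELF"
        assert res.multiple_r == pytest.approx(1.0)

    def test_signed_r_carries_slope_sign(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=40)
        y = pd.Series(-z + 0.3 * rng.normal(size=40), index=range(40))
        cands = {"Z": pd.Series(z, index=y.index),
                 "N": pd.Series(rng.normal(size=40), index=y.index)}
        res = stepwise_forward(y, cands)
        assert res.selected == ["Z"]
        assert res.signed_r < -0.8
        assert res.multiple_r > 0.8

    def test_collinear_candidate_skipped(self):
        rng = np.random.default_rng(9)
        z = pd.Series(rng.normal(size=40), index=range(40))
        y = z + 0.1 * rng.normal(size=40)
        cands = {"Z": z, "Z2": 2 * z + 1, "N": pd.Series(rng.normal(size=40), index=z.index)}
        with pytest.warns(UserWarning, match="collinear"):
            res = stepwise_forward(y, cands)
        assert "Z" in res.selected and "Z2" not in res.selected

    def test_entry_pvalues_below_threshold(self):
        rng = np.random.default_rng(10)
        z1, z2 = rng.normal(size=50), rng.normal(size=50)
        y = pd.Series(z1 + 0.5 * z2 + 0.3 * rng.normal(size=50), index=range(50))
        cands = {
            "Z1": pd.Series(z1, index=y.index),
            "Z2": pd.Series(z2, index=y.index),
            "N": pd.Series(rng.normal(size=50), index=y.index),
        }
        res = stepwise_forward(y, cands, p_enter=0.05)
        assert set(res.selected) >= {"Z1", "Z2"}
        assert all(p < 0.05 for p in res.entry_pvalues.values())


class TestPrewhiten:
    def test_removes_ar1_structure(self):
        from sclerochron.crossdate import first_order_autocorrelation

        rng = np.random.default_rng(11)
        x = np.zeros(5000)
        eps = rng.normal(size=5000)
        for t in range(1, 5000):
            x[t] = 0.7 * x[t - 1] + eps[t]
        res = prewhiten_ar1(pd.Series(x))
        assert len(res) == 4999
        assert abs(first_order_autocorrelation(res.to_numpy())) < 0.05

    def test_white_noise_nearly_unchanged(self):
        rng = np.random.default_rng(12)
        x = pd.Series(rng.normal(size=2000))
        res = prewhiten_ar1(x)
        # phi-hat ~ 0, so residuals track the (shifted) input
        assert np.corrcoef(res.to_numpy(), x.to_numpy()[1:])[0, 1] > 0.99

    def test_mean_restored(self):
        rng = np.random.default_rng(13)
        x = pd.Series(5.0 + rng.normal(size=500))
        assert prewhiten_ar1(x).mean() == pytest.approx(x.mean(), abs=1e-9)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            prewhiten_ar1(pd.Series(np.ones(50)))


class TestAnalysisReport:
    def test_end_to_end_and_reproducible(self, chronology_result, default_driver):
        rng = np.random.default_rng(14)
        idx = default_driver.data.index
        variables = {
            "DRV": default_driver,
            "N1": sc.MonthlySeries(
                name="N1", data=pd.Series(rng.normal(10, 1, len(idx)), index=idx)
            ),
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep1 = analysis_report(chronology_result.series, variables)
            rep2 = analysis_report(chronology_result.series, variables)
        assert rep1.stepwise.selected  # the driver carries real signal
        assert rep1.stepwise_prewhitened is not None
        assert rep1.to_json() == rep2.to_json()
        payload = json.loads(rep1.to_json())
        assert set(payload) >= {"stepwise", "stepwise_prewhitened", "overlap_years"}
        tab = rep1.correlations.table
        assert len(tab) == 2 * 18
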