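"""Shared fixtures: one default synthetic study reused across test modules."""

import warnings

import numpy as np
import pytest

import sclerochron as sc


@pytest.fixture(scope="session")
def default_driver():
    return sc.simulate_environment_monthly(1935, 2016, seed=1)


@pytest.fixture(scope="session")
def default_study(default_driver):
    """(collection, true_signal) for the default 30-shell scenario, seed 1."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sc.simulate_shell_collection(sc.SimConfig(seed=1), default_driver)


@pytest.fixture(scope="session")
def chronology_result(default_study):
    coll, _ = default_study
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sc.ChronologyModel(coll).fit()


@pytest.fixture(scope="session")
def truncation_fixture():
    """Collection engineered so depth passes 10 in 1973 and the running EPS
    becomes adequate only for windows starting in 1979: four long series
    from 1954 and eight from 1973, sharing a unit-variance common signal
    from 1979 on, while pre-1979 years hold large anticorrelated-group
    values that destroy the window rbar wherever they intrude."""
    rng = np.random.default_rng(0)
    years = np.arange(1954, 2017)
    sig = rng.normal(size=len(years))
    series = []
    starts = [1954] * 4 + [1973] * 8
    for i, st in enumerate(starts):
        yrs = np.arange(st, 2017)
        v = sig[yrs - 1954] + 0.2 * rng.normal(size=len(yrs))
        bad = yrs < 1979
        group = 1.0 if i % 2 == 0 else -1.0
        ct = np.where(yrs % 2 == 0, 1.0, -1.0)
        v[bad] = group * 30.0 * ct[bad]
        series.append(
            sc.DetrendedSeries(
                specimen_id=f"F{i:02d}", first_year=int(st), indices=v, mode="residual"
            )
        )
    return sc.SeriesCollection(series)
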