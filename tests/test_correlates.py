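"""OLS regressions of richness on sampling covariates and sea level."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from conftest import small_synthetic_config
from oracles import ols_by_hand

from palaeodiv.correlates import (interval_length_series, regress,
                                  regression_suite, sea_level_per_interval,
                                  suite_to_frame)
from palaeodiv.grid import build_grid
from palaeodiv.occurrences import clean_occurrences
from palaeodiv.synthetic import generate_occurrences, scenario


def _series(values):
    return {f"I{i}": v for i, v in enumerate(values)}


def test_perfect_linear_fit():
    x = _series([1, 2, 3, 4, 5])
    y = _series([3, 5, 7, 9, 11])  # y = 2x + 1
    r = regress(y, x)
    assert r.slope == pytest.approx(2.0)
    assert r.intercept == pytest.approx(1.0)
    assert r.r_squared == pytest.approx(1.0)
    assert r.n == 5


def test_hand_computed_r_squared():
    # closed-form least squares: slope 0.5, R^2 = 0.25
    r = regress(_series([1, 3, 2]), _series([1, 2, 3]))
    assert r.slope == pytest.approx(0.5)
    assert r.r_squared == pytest.approx(0.25)


def test_r_squared_equals_squared_pearson_on_random_fits():
    rng = np.random.default_rng(13)
    for _ in range(300):
        n = int(rng.integers(4, 12))
        x = rng.normal(size=n)
        y = rng.normal(size=n) + rng.uniform(-2, 2) * x
        r = regress(_series(y), _series(x))
        rho = pearsonr(x, y).statistic
        assert r.r_squared == pytest.approx(rho ** 2, abs=1e-10)
        slope, intercept, r2 = ols_by_hand(list(x), list(y))
        assert r.slope == pytest.approx(slope)
        assert r.intercept == pytest.approx(intercept)
        assert r.r_squared == pytest.approx(r2)


def test_affine_rescaling_of_x_preserves_r2_and_p():
    rng = np.random.default_rng(14)
    x = rng.uniform(0, 50, 10)
    y = 2 * x + rng.normal(0, 5, 10)
    base = regress(_series(y), _series(x))
    scaled = regress(_series(y), _series(4.0 * x + 7.0))
    assert scaled.r_squared == pytest.approx(base.r_squared)
    assert scaled.p_value == pytest.approx(base.p_value)
    assert scaled.slope == pytest.approx(base.slope / 4.0)


def test_pairwise_dropping_bookkeeping():
    y = {"a": 1.0, "b": 2.0, "c": 3.0, "d": np.nan, "e": 5.0}
    x = {"a": 1.0, "b": 2.0, "c": 2.5, "e": 4.0, "f": 9.0}
    r = regress(y, x)
    assert r.n == 4
    assert r.n + r.n_dropped == len(set(y) | set(x))


def test_degenerate_inputs_rejected():
    with pytest.raises(ValueError, match="zero variance"):
        regress(_series([1, 2, 3]), _series([5, 5, 5]), x_name="localities")
    with pytest.raises(ValueError, match=">= 3"):
        regress(_series([1, 2]), _series([1, 2]))


def test_sea_level_aggregation(equal_length):
    ivs = equal_length[:4]
    span = np.arange(ivs[-1].end_ma + 0.05, ivs[0].start_ma, 0.1)
    const = sea_level_per_interval(span, np.full_like(span, 100.0), ivs)
    assert all(v == pytest.approx(100.0) for v in const.values.values())
    mid = sea_level_per_interval(span, np.full_like(span, 100.0), ivs,
                                 method="midpoint")
    assert all(v == pytest.approx(100.0) for v in mid.values.values())

    # linear ramp: within-bin mean ~= value at the bin midpoint
    ramp = sea_level_per_interval(span, 2.0 * span, ivs)
    for iv in ivs:
        assert ramp.values[iv.id] == pytest.approx(
            iv.start_ma + iv.end_ma, rel=1e-3)

    # irregular series against a brute-force average
    rng = np.random.default_rng(5)
    ages = rng.uniform(ivs[-1].end_ma, ivs[0].start_ma, 200)
    lev = rng.normal(0, 30, 200)
    got = sea_level_per_interval(ages, lev, ivs)
    for iv in ivs:
        sel = [l for a, l in zip(ages, lev) if iv.end_ma <= a < iv.start_ma]
        assert got.values[iv.id] == pytest.approx(sum(sel) / len(sel))


def test_sea_level_missing_coverage_is_an_error(equal_length):
    ivs = equal_length[:3]
    ages = np.linspace(ivs[1].end_ma, ivs[0].start_ma - 0.01, 50)
    with pytest.raises(ValueError, match=ivs[2].id):
        sea_level_per_interval(ages, np.zeros(50), ivs)


def test_interval_length_series(equal_length):
    s = interval_length_series(equal_length)
    assert s.values["EL11"] == pytest.approx(7.7)


def test_suite_panels_and_determinism(ts, equal_length):
    cfg = scenario("flat_diversity_varying_effort")
    t, _ = generate_occurrences(cfg)
    t = clean_occurrences(t)
    grid = build_grid(50.0)
    span = np.arange(equal_length[-1].end_ma, equal_length[0].start_ma + 1, 0.5)
    rng = np.random.default_rng(6)
    sea = sea_level_per_interval(span, rng.normal(0, 40, span.size),
                                 equal_length)
    s1 = regression_suite(t, equal_length, ts, grid, sea_level=sea)
    s2 = regression_suite(t, equal_length, ts, grid, sea_level=sea)
    assert set(s1) == {
        "localities", "geological_units", "grid_cells", "interval_length",
        "sea_level", "sea_level_freshwater", "sea_level_marine",
        "sea_level_excl_devonian", "sea_level_freshwater_excl_devonian"}
    assert s1 == s2
    # effort-driven fixture: the richness-localities panel is significant
    assert s1["localities"].slope > 0 and s1["localities"].p_value < 0.05
    frame = suite_to_frame(s1)
    assert set(frame.columns) >= {"panel", "slope", "r_squared", "p_value", "n"}


def test_suite_without_sea_level_warns_and_skips(ts, equal_length):
    rng = np.random.default_rng(15)
    cfg = small_synthetic_config(rng, equal_length, seed=8)
    t, _ = generate_occurrences(cfg)
    with pytest.warns(UserWarning, match="sea-level"):
        suite = regression_suite(t, equal_length, ts, build_grid(100.0))
    assert set(suite) == {"localities", "geological_units", "grid_cells",
                          "interval_length"}
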