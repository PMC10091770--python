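"""Ordinary least-squares fits of richness against sampling covariates.

Each fit is a simple untransformed OLS of per-interval richness on one
covariate: a sampling proxy (localities, geological units, occupied grid
cells), interval length, or eustatic sea level.  The reported statistics
are the slope, intercept, coefficient of determination R², the two-sided
p-value for the slope t-test (n−2 df; equivalent to the F test in simple
regression), and the number of intervals used after pairwise dropping.

The full suite comprises nine panels: overall genus richness against
the three proxies, interval length and sea level,
plus freshwater-only and marine-only richness against sea level, and the
sea-level fits repeated with Devonian bins excluded.  A significant
richness–proxy slope is the classic symptom of a sampling-driven
face-value curve; a sea-level correlate bears on the common-cause
hypothesis.  No multiple-testing adjustment or autocorrelation
correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .binning import assign_to_intervals
from .diversity import (ProxySeries, RichnessSeries, richness_per_interval,
                        sampling_proxies_per_interval, subset_occurrences)
from .grid import EqualAreaGrid
from .occurrences import OccurrenceTable
from .timescale import CompositeInterval, Timescale

__all__ = ["RegressionResult", "CovariateSeries", "regress",
           "interval_length_series", "sea_level_per_interval",
           "regression_suite", "suite_to_frame", "DEVONIAN_END_MA"]

#: end-Devonian boundary; bins entirely older than this are "Devonian"
DEVONIAN_END_MA = 358.9


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    n_dropped: int = 0

    def summary_row(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept,
                "r_squared": self.r_squared, "p_value": self.p_value,
                "n": self.n}


@dataclass
class CovariateSeries:
    scheme_id: str
    name: str
    values: dict[str, float]


def regress(y: Mapping[str, float], x: Mapping[str, float],
            x_name: str = "x", log_y: bool = False) -> RegressionResult:
    """Simple OLS of y on x over shared interval keys.

    Intervals missing (or NaN) on either side are dropped pairwise.
    ``log_y`` fits log(y + 1) instead of raw counts (off by default).
    """
    def _values(obj) -> dict:
        if isinstance(obj, (RichnessSeries, ProxySeries, CovariateSeries)):
            return obj.values
        return dict(obj)

    yv = _values(y)
    xv = _values(x)
    keys = [k for k in yv if k in xv]
    pairs = [(float(yv[k]), float(xv[k])) for k in keys
             if np.isfinite(yv[k]) and np.isfinite(xv[k])]
    n_dropped = len(set(yv) | set(xv)) - len(pairs)
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 shared intervals, have {len(pairs)}")
    arr_y = np.array([p[0] for p in pairs])
    arr_x = np.array([p[1] for p in pairs])
    if np.ptp(arr_x) == 0:
        raise ValueError(f"covariate {x_name!r} has zero variance")
    if log_y:
        arr_y = np.log(arr_y + 1.0)
    fit = sm.OLS(arr_y, sm.add_constant(arr_x)).fit()
    return RegressionResult(
        slope=float(fit.params[1]), intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared), p_value=float(fit.pvalues[1]),
        n=len(pairs), n_dropped=n_dropped)


def interval_length_series(intervals: Sequence[CompositeInterval],
                           scheme_id: str = "scheme") -> CovariateSeries:
    return CovariateSeries(scheme_id, "interval_length",
                           {iv.id: iv.duration_myr for iv in intervals})


def sea_level_per_interval(ages_ma: Sequence[float],
                           levels: Sequence[float],
                           intervals: Sequence[CompositeInterval],
                           method: str = "mean",
                           scheme_id: str = "scheme") -> CovariateSeries:
    """Aggregate a sea-level time series to one value per interval.

    ``mean`` averages the samples whose ages fall in the interval (the
    default); ``midpoint`` linearly interpolates the series at the
    interval midpoint.  An interval not covered by the series raises.
    """
    ages = np.asarray(ages_ma, dtype=float)
    lev = np.asarray(levels, dtype=float)
    if ages.shape != lev.shape or ages.size == 0:
        raise ValueError("ages and levels must be equal-length, non-empty")
    order = np.argsort(ages)
    ages, lev = ages[order], lev[order]
    values: dict[str, float] = {}
    uncovered = []
    for iv in intervals:
        if method == "mean":
            mask = (ages >= iv.end_ma) & (ages < iv.start_ma)
            if not mask.any():
                uncovered.append(iv.id)
                continue
            values[iv.id] = float(lev[mask].mean())
        elif method == "midpoint":
            mid = (iv.start_ma + iv.end_ma) / 2.0
            if mid < ages[0] or mid > ages[-1]:
                uncovered.append(iv.id)
                continue
            values[iv.id] = float(np.interp(mid, ages, lev))
        else:
            raise ValueError(f"unknown method {method!r}")
    if uncovered:
        raise ValueError(
            f"sea-level series does not cover intervals {uncovered}")
    return CovariateSeries(scheme_id, "sea_level", values)


def _non_devonian(intervals: Sequence[CompositeInterval]
                  ) -> list[CompositeInterval]:
    return [iv for iv in intervals if iv.end_ma < DEVONIAN_END_MA]


def regression_suite(t: OccurrenceTable,
                     intervals: Sequence[CompositeInterval],
                     ts: Timescale,
                     grid: EqualAreaGrid,
                     sea_level: CovariateSeries | None = None,
                     policy: str = "strict",
                     scheme_id: str = "scheme"
                     ) -> dict[str, RegressionResult]:
    """The nine-panel suite of genus-richness regressions.

    Panels: richness vs (A) localities, (B) geological units, (C) grid
    cells, (D) interval length, (E) sea level; (F) freshwater and (G)
    marine richness vs sea level; (H) overall and (I) freshwater richness
    vs sea level excluding Devonian bins.  Panels E-I are skipped with a
    warning when no sea-level series is supplied.
    """
    b = assign_to_intervals(t, intervals, ts, policy=policy,
                            scheme_id=scheme_id)
    rich = richness_per_interval(b, t, rank="genus")
    proxies = {p.metric: p
               for p in sampling_proxies_per_interval(b, t, grid)}
    out: dict[str, RegressionResult] = {}
    out["localities"] = regress(rich, proxies["localities"], "localities")
    out["geological_units"] = regress(
        rich, proxies["geological_units"], "geological_units")
    out["grid_cells"] = regress(rich, proxies["grid_cells"], "grid_cells")
    out["interval_length"] = regress(
        rich, interval_length_series(intervals, scheme_id), "interval_length")

    if sea_level is None:
        warnings.warn("no sea-level series supplied; skipping panels E-I",
                      stacklevel=2)
        return out

    out["sea_level"] = regress(rich, sea_level, "sea_level")

    def env_richness(env: str, ivs: Sequence[CompositeInterval]
                     ) -> RichnessSeries:
        sub = subset_occurrences(t, environment=env)
        bb = assign_to_intervals(sub, ivs, ts, policy=policy,
                                 scheme_id=scheme_id)
        return richness_per_interval(bb, sub, rank="genus")

    out["sea_level_freshwater"] = regress(
        env_richness("freshwater", intervals), sea_level, "sea_level")
    out["sea_level_marine"] = regress(
        env_richness("marine", intervals), sea_level, "sea_level")

    post = _non_devonian(intervals)
    b_post = assign_to_intervals(t, post, ts, policy=policy,
                                 scheme_id=scheme_id)
    rich_post = richness_per_interval(b_post, t, rank="genus")
    out["sea_level_excl_devonian"] = regress(rich_post, sea_level, "sea_level")
    out["sea_level_freshwater_excl_devonian"] = regress(
        env_richness("freshwater", post), sea_level, "sea_level")
    return out


def suite_to_frame(suite: Mapping[str, RegressionResult]) -> pd.DataFrame:
    """Results table: one row per panel with slope, R², p and n."""
    rows = []
    for name, res in suite.items():
        row = {"panel": name}
        row.update(res.summary_row())
        rows.append(row)
    return pd.DataFrame(rows)
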