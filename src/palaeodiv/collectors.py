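"""Collector's curves: cumulative species descriptions through time.

A collector's curve plots the cumulative number of species described as
a function of publication year; a plateau suggests the described fauna
is approaching saturation, while sustained acceleration indicates an
undersampled record.  Each species is counted once, at the earliest
description year across its records, and (for regional curves) is
attributed to the region of that earliest-described record, with ties
broken alphabetically by region name.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .occurrences import OccurrenceTable, species_determinate

__all__ = ["CumulativeCurve", "collectors_curve", "curves_to_frame"]


@dataclass
class CumulativeCurve:
    group: str                 # "global" or a region name
    years: np.ndarray          # strictly increasing
    counts: np.ndarray         # non-decreasing cumulative species totals

    def final_count(self) -> int:
        return int(self.counts[-1]) if len(self.counts) else 0

    def densify(self, year_min: int | None = None,
                year_max: int | None = None) -> pd.DataFrame:
        """Step-fill the sparse curve to one row per calendar year."""
        if not len(self.years):
            return pd.DataFrame(columns=["year", "cumulative_count"])
        y0 = int(year_min if year_min is not None else self.years[0])
        y1 = int(year_max if year_max is not None else self.years[-1])
        grid_years = np.arange(y0, y1 + 1)
        idx = np.searchsorted(self.years, grid_years, side="right") - 1
        counts = np.where(idx >= 0, self.counts[np.clip(idx, 0, None)], 0)
        return pd.DataFrame({"year": grid_years, "cumulative_count": counts})


def _first_descriptions(t: OccurrenceTable) -> pd.DataFrame:
    """One row per species: earliest description year and its region."""
    df = t.df
    det = species_determinate(df) & df["year_described"].notna()
    sub = df[det].copy()
    sub["binomial"] = sub["genus"] + " " + sub["species"]
    sub = sub.sort_values(["binomial", "year_described", "region"],
                          kind="mergesort")
    return sub.drop_duplicates("binomial")[
        ["binomial", "year_described", "region"]]


def collectors_curve(t: OccurrenceTable,
                     by_region: bool = False) -> list[CumulativeCurve]:
    """Global (and optionally per-region) cumulative description curves.

    Species lacking a description year are excluded.  Regional curves'
    final counts sum exactly to the global final count, since each
    species is attributed to exactly one region.
    """
    firsts = _first_descriptions(t)
    curves = [_cumulate("global", firsts)]
    if by_region:
        for region, grp in firsts.groupby("region", sort=True):
            curves.append(_cumulate(region if region else "unknown", grp))
    return curves


def _cumulate(group: str, firsts: pd.DataFrame) -> CumulativeCurve:
    per_year = firsts.groupby("year_described").size().sort_index()
    years = per_year.index.to_numpy(dtype=int)
    counts = per_year.to_numpy().cumsum()
    return CumulativeCurve(group=group, years=years, counts=counts)


def curves_to_frame(curves: list[CumulativeCurve]) -> pd.DataFrame:
    """Tidy export: group, year, cumulative_count."""
    rows = []
    for c in curves:
        for y, n in zip(c.years, c.counts):
            rows.append({"group": c.group, "year": int(y),
                         "cumulative_count": int(n)})
    return pd.DataFrame(rows, columns=["group", "year", "cumulative_count"])
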