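"""Per-interval sampled-in-bin richness and sampling-effort proxies.

*Sampled-in-bin* richness counts the distinct taxa whose occurrences fall
in a time bin, with no range interpolation between bins — the face-value
diversity curve.  Genus-level counts include records determinate at genus
level only; species-level counts use full binomials among
species-determinate records.

Three per-bin sampling proxies accompany the richness series: unique
geographic localities, unique geological units (formation preferred over
member/group), and occupied equal-area grid cells.  Where these proxies
and richness move together, the "signal" in a face-value curve may be
sampling effort rather than diversity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .binning import BinnedOccurrences, resolve_spans
from .grid import EqualAreaGrid
from .occurrences import (ENVIRONMENTS, REGIONS, OccurrenceTable,
                          locality_keys, species_determinate)
from .timescale import CompositeInterval, Timescale

__all__ = ["RichnessSeries", "ProxySeries", "richness_per_interval",
           "sampling_proxies_per_interval", "subset_occurrences",
           "series_to_frame"]

PROXY_METRICS = ("localities", "geological_units", "grid_cells")


@dataclass
class RichnessSeries:
    scheme_id: str
    rank: str                  # "genus" | "species"
    values: dict[str, int]     # interval_id -> count, zeros included


@dataclass
class ProxySeries:
    scheme_id: str
    metric: str                # one of PROXY_METRICS
    values: dict[str, int]


def _joined(b: BinnedOccurrences, t: OccurrenceTable) -> pd.DataFrame:
    return b.assignments.merge(t.df, on="occurrence_id", how="left")


def richness_per_interval(b: BinnedOccurrences, t: OccurrenceTable,
                          rank: str = "genus") -> RichnessSeries:
    """Distinct genera (or species binomials) per composite interval."""
    if rank not in ("genus", "species"):
        raise ValueError(f"rank must be 'genus' or 'species', got {rank!r}")
    df = _joined(b, t)
    if rank == "genus":
        df = df[df["genus"] != ""]
        taxon = df["genus"]
    else:
        det = species_determinate(df)
        df = df[det]
        taxon = df["genus"] + " " + df["species"]
    counts = taxon.groupby(df["interval_id"]).nunique()
    values = {iid: int(counts.get(iid, 0)) for iid in b.interval_ids}
    return RichnessSeries(scheme_id=b.scheme_id, rank=rank, values=values)


def sampling_proxies_per_interval(b: BinnedOccurrences, t: OccurrenceTable,
                                  grid: EqualAreaGrid) -> list[ProxySeries]:
    """Localities, geological units and occupied grid cells per interval.

    Deduplication is within-bin only: a locality sampled in two bins
    counts once in each.  Records without coordinates are excluded from
    the grid-cell proxy only.
    """
    df = _joined(b, t)
    loc = locality_keys(df).groupby(df["interval_id"]).nunique()
    units = df.loc[df["geological_unit"] != "", "geological_unit"].str.lower()
    unit_counts = units.groupby(df["interval_id"]).nunique()

    has_xy = df["latitude"].notna() & df["longitude"].notna()
    dfg = df[has_xy]
    cells = pd.Series(
        [grid.cell_of(la, lo) for la, lo in zip(dfg["latitude"], dfg["longitude"])],
        index=dfg.index, dtype=object)
    cell_counts = cells.groupby(dfg["interval_id"]).nunique()

    def fill(counts: pd.Series) -> dict[str, int]:
        return {iid: int(counts.get(iid, 0)) for iid in b.interval_ids}

    return [
        ProxySeries(b.scheme_id, "localities", fill(loc)),
        ProxySeries(b.scheme_id, "geological_units", fill(unit_counts)),
        ProxySeries(b.scheme_id, "grid_cells", fill(cell_counts)),
    ]


def subset_occurrences(t: OccurrenceTable,
                       environment: str | None = None,
                       region: str | None = None,
                       exclude_localities: Sequence[str] = (),
                       exclude_intervals: Sequence[CompositeInterval] = (),
                       ts: Timescale | None = None) -> OccurrenceTable:
    """Filter an occurrence table by environment, region, locality or age.

    ``exclude_localities`` matches locality names case-insensitively as
    substrings, so "Bear Gulch" removes every Bear Gulch Limestone site.
    ``exclude_intervals`` drops records whose resolved age span overlaps
    any of the given intervals (requires ``ts``).
    """
    df = t.df
    keep = pd.Series(True, index=df.index)
    note = []
    if environment is not None:
        if environment not in ENVIRONMENTS:
            raise ValueError(f"unknown environment {environment!r}")
        keep &= df["environment"] == environment
        note.append(f"environment={environment}")
    if region is not None:
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        keep &= df["region"] == region
        note.append(f"region={region}")
    if exclude_localities:
        lowered = df["locality_name"].str.lower()
        for name in exclude_localities:
            keep &= ~lowered.str.contains(str(name).lower(), regex=False)
        note.append(f"exclude_localities={list(exclude_localities)}")
    if len(exclude_intervals):
        if ts is None:
            raise ValueError("exclude_intervals requires a Timescale")
        old, young, reasons = resolve_spans(df, ts)
        overlap = pd.Series(False, index=df.index)
        for pos, (o, y, r) in enumerate(zip(old, young, reasons)):
            if r is not None:
                continue
            for iv in exclude_intervals:
                if (o == y and iv.contains_age(o)) or \
                        (o != y and y < iv.start_ma and o > iv.end_ma):
                    overlap.iloc[pos] = True
                    break
        keep &= ~overlap
        note.append(
            f"exclude_intervals={[iv.id for iv in exclude_intervals]}")
    return t.with_df(df[keep], "subset: " + ", ".join(note) if note else "subset")


def series_to_frame(series: RichnessSeries | ProxySeries) -> pd.DataFrame:
    """Tidy export: scheme_id, interval_id, metric/rank, value."""
    kind = series.rank if isinstance(series, RichnessSeries) else series.metric
    return pd.DataFrame({
        "scheme_id": series.scheme_id,
        "interval_id": list(series.values),
        "metric": kind,
        "value": list(series.values.values()),
    })
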