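"""Independent brute-force oracles for cross-checking the library.

Deliberately naive: nested loops and exhaustive scans, no shared code
with the implementations they check.
"""

from __future__ import annotations

import math


def distinct_count(items) -> int:
    """Distinct non-empty items by nested-loop comparison (no sets)."""
    seen = []
    for it in items:
        if it == "" or it is None:
            continue
        is_new = True
        for s in seen:
            if s == it:
                is_new = False
                break
        if is_new:
            seen.append(it)
    return len(seen)


def richness_by_bin(records, assignments, rank: str) -> dict:
    """records: occurrence_id -> (genus, species, qualifier);
    assignments: list of (occurrence_id, interval_id)."""
    out: dict[str, int] = {}
    bins = sorted({iid for _, iid in assignments})
    for iid in bins:
        taxa = []
        for oid, bid in assignments:
            if bid != iid:
                continue
            g, s, q = records[oid]
            if q == "indet" or g == "":
                continue
            if rank == "genus":
                taxa.append(g)
            elif s != "":
                taxa.append(g + " " + s)
        out[iid] = distinct_count(taxa)
    return out


def overlapping_intervals(span_old: float, span_young: float,
                          intervals) -> list[str]:
    """All intervals a half-open [young, old) span intersects."""
    hits = []
    for iv in intervals:
        if span_old == span_young:
            if iv.end_ma <= span_old < iv.start_ma:
                hits.append(iv.id)
        elif span_young < iv.start_ma and span_old > iv.end_ma:
            hits.append(iv.id)
    return hits


def cell_by_exhaustive_search(grid, lat: float, lon: float):
    """Locate a point by scanning every cell's bounds."""
    s = math.sin(math.radians(lat))
    u = ((lon + 180.0) % 360.0) / 360.0
    for b in range(grid.n_bands):
        lo, hi = grid.sin_bounds[b], grid.sin_bounds[b + 1]
        in_band = (lo < s <= hi) if b > 0 else (s <= hi)
        if not in_band:
            continue
        k = int(grid.cells_per_band[b])
        for c in range(k):
            clo, chi = c / k, (c + 1) / k
            in_cell = (clo < u <= chi) if c > 0 else (u <= chi)
            if in_cell:
                return (b, c)
    raise AssertionError(f"point ({lat}, {lon}) unassigned by brute force")


def cell_area_km2(grid, band: int) -> float:
    """Closed-form spherical area of one cell of a band."""
    import palaeodiv.grid as g
    r = g.EARTH_RADIUS_KM
    lo, hi = grid.sin_bounds[band], grid.sin_bounds[band + 1]
    band_area = 2.0 * math.pi * r * r * (hi - lo)
    return band_area / int(grid.cells_per_band[band])


def ols_by_hand(xs, ys):
    """Simple least squares via the closed-form normal equations."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxx = sum((x - mx) ** 2 for x in xs)
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    slope = sxy / sxx
    intercept = my - slope * mx
    sse = sum((y - (intercept + slope * x)) ** 2 for x, y in zip(xs, ys))
    sst = sum((y - my) ** 2 for y in ys)
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return slope, intercept, r2
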