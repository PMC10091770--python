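"""Assigning occurrences to composite time bins.

Dating resolution order per record: regional substage span if present,
else ICS stage span, else the numeric ``[min_ma, max_ma]`` range.  The
substage wins even when its span falls outside the named stage — database
stage fields are sometimes inconsistent with the (more trustworthy)
regional substage, as with Arnsbergian localities filed under the
Bashkirian that belong in the Serpukhovian.

Assignment policies:

``strict`` (default)
    assign only when the dated span lies within a single interval;
    spans straddling a bin boundary are left unassigned.
``all_overlapping``
    assign to every interval the span intersects.
``midpoint``
    assign to the interval containing the span midpoint.

Spans are half-open ``[end_ma, start_ma)`` like the intervals themselves,
so a stage span coincident with a bin tiles it exactly and touches no
neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .occurrences import OccurrenceTable
from .timescale import CompositeInterval, Timescale

__all__ = ["BinnedOccurrences", "assign_to_intervals", "resolve_spans",
           "POLICIES"]

POLICIES = ("strict", "all_overlapping", "midpoint")


@dataclass
class BinnedOccurrences:
    """Interval assignments plus the unassigned remainder.

    Every occurrence of the input table appears exactly once in
    ``assignments`` (possibly several times under ``all_overlapping``) or
    once in ``unassigned``, never both.
    """

    assignments: pd.DataFrame   # occurrence_id, interval_id
    unassigned: pd.DataFrame    # occurrence_id, reason
    scheme_id: str
    policy: str
    interval_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        out = self.assignments.copy()
        out["policy"] = self.policy
        out["scheme_id"] = self.scheme_id
        return out

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def resolve_spans(df: pd.DataFrame, ts: Timescale
                  ) -> tuple[np.ndarray, np.ndarray, list[str | None]]:
    """Resolve each record to an age span (old, young) in Ma.

    Returns (older bounds, younger bounds, per-row failure reason or None).
    Unknown substage/stage names are reported, not silently ignored.
    """
    n = len(df)
    old = np.full(n, np.nan)
    young = np.full(n, np.nan)
    reasons: list[str | None] = [None] * n
    substage = df["substage"].astype(str).str.strip()
    stage = df["stage"].astype(str).str.strip()
    for i, (ss, st, mx, mn) in enumerate(
            zip(substage, stage, df["max_ma"], df["min_ma"])):
        if ss:
            if ts.has_substage(ss):
                s = ts.substage(ss)
                old[i], young[i] = s.start_ma, s.end_ma
            else:
                reasons[i] = f"unknown substage {ss!r}"
        elif st:
            if ts.has_stage(st):
                s = ts.stage(st)
                old[i], young[i] = s.start_ma, s.end_ma
            else:
                reasons[i] = f"unknown stage {st!r}"
        elif pd.notna(mx) and pd.notna(mn):
            old[i], young[i] = float(mx), float(mn)
        else:
            reasons[i] = "no age information"
    return old, young, reasons


def _span_assign(old: float, young: float,
                 ivs: Sequence[CompositeInterval],
                 policy: str) -> tuple[list[str], str | None]:
    """Intervals hit by one half-open span [young, old) under a policy.

    Returns (interval ids, failure reason or None).
    """
    if old == young:  # point age: half-open membership, older bin at ties
        hits = [iv.id for iv in ivs if iv.contains_age(old)]
        return (hits, None) if hits else ([], "age outside scheme")
    overlapping = [iv for iv in ivs if young < iv.start_ma and old > iv.end_ma]
    if not overlapping:
        return [], "span outside scheme"
    if policy == "all_overlapping":
        return [iv.id for iv in overlapping], None
    if policy == "midpoint":
        mid = (old + young) / 2.0
        hits = [iv.id for iv in ivs if iv.contains_age(mid)]
        return (hits[:1], None) if hits else ([], "midpoint outside scheme")
    if policy == "strict":
        # non-overlapping intervals: a span can lie inside at most one
        inside = [iv for iv in overlapping
                  if iv.end_ma <= young and old <= iv.start_ma]
        if inside:
            return [inside[0].id], None
        return [], "span straddles multiple intervals"
    raise ValueError(f"unknown policy {policy!r}")


def assign_to_intervals(t: OccurrenceTable,
                        scheme: Sequence[CompositeInterval],
                        ts: Timescale,
                        policy: str = "strict",
                        scheme_id: str = "scheme") -> BinnedOccurrences:
    """Place each occurrence in composite interval(s) under a policy."""
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {POLICIES}")
    ivs = sorted(scheme, key=lambda iv: -iv.start_ma)
    for a, b in zip(ivs, ivs[1:]):
        if a.end_ma - b.start_ma > 1e-6:
            raise ValueError(f"scheme has a gap between {a.id!r} and {b.id!r}")
    old, young, reasons = resolve_spans(t.df, ts)

    # cache per unique span: records dated the same way bin the same way
    cache: dict[tuple[float, float], tuple[list[str], str | None]] = {}
    rows_a, rows_u = [], []
    for i, oid in enumerate(t.df["occurrence_id"]):
        if reasons[i] is not None:
            rows_u.append({"occurrence_id": oid, "reason": reasons[i]})
            continue
        key = (old[i], young[i])
        if key not in cache:
            cache[key] = _span_assign(old[i], young[i], ivs, policy)
        hit, fail = cache[key]
        if fail is not None:
            rows_u.append({"occurrence_id": oid, "reason": fail})
        else:
            for iid in hit:
                rows_a.append({"occurrence_id": oid, "interval_id": iid})
    return BinnedOccurrences(
        assignments=pd.DataFrame(rows_a, columns=["occurrence_id", "interval_id"]),
        unassigned=pd.DataFrame(rows_u, columns=["occurrence_id", "reason"]),
        scheme_id=scheme_id, policy=policy,
        interval_ids=[iv.id for iv in ivs],
    )
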