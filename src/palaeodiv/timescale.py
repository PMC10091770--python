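"""Geological timescale handling and composite time-bin construction.

Palaeozoic stage lengths are wildly unequal (the Kasimovian spans 3.3 Myr,
the Visean 15.8 Myr), and interval length can itself distort richness
trends.  This module houses an editable table of ICS stage boundary ages
(Lochkovian-Changhsingian), a concordance of regional substages (British
Dinantian/Namurian usage plus the Bohemian Emsian subdivisions), and a
builder for *composite intervals*: time bins of roughly equal (~9 Myr)
length obtained by merging short stages and splitting long ones at
substage boundaries.

All ages are Ma before present, positive, older = larger.  Interval
membership uses half-open spans ``[end_ma, start_ma)`` that include the
younger bound, so a datum dated exactly to a stage boundary falls in the
older bin — a deterministic tie-break the literature leaves unstated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

__all__ = [
    "Stage",
    "SubstageSpan",
    "CompositeInterval",
    "Timescale",
    "TimescaleError",
    "load_timescale",
    "load_default_timescale",
    "build_composite_intervals",
    "load_scheme",
    "load_default_scheme",
    "stage_identity_scheme",
    "write_scheme",
]

#: tolerance (Myr) for contiguity of adjacent spans
_TOL = 1e-6

TableSource = Union[str, Path, pd.DataFrame]


class TimescaleError(ValueError):
    """Raised for gaps, overlaps, or unknown stage/substage names."""


@dataclass(frozen=True)
class Stage:
    name: str
    period: str
    start_ma: float  # older bound
    end_ma: float    # younger bound

    def __post_init__(self) -> None:
        if not (self.start_ma > self.end_ma > 0):
            raise TimescaleError(
                f"stage {self.name!r}: require start_ma > end_ma > 0, "
                f"got {self.start_ma}-{self.end_ma}"
            )

    @property
    def duration_myr(self) -> float:
        return self.start_ma - self.end_ma


@dataclass(frozen=True)
class SubstageSpan:
    """A regional substage (e.g. Asbian, Arnsbergian) pinned to numeric ages.

    The span may legitimately straddle its nominal parent stage: some
    database records carry a stage name inconsistent with their regional
    substage, and the substage placement is the more trustworthy one.
    """

    name: str
    parent_stage: str
    start_ma: float
    end_ma: float

    def __post_init__(self) -> None:
        if not (self.start_ma > self.end_ma > 0):
            raise TimescaleError(
                f"substage {self.name!r}: require start_ma > end_ma > 0"
            )


@dataclass(frozen=True)
class CompositeInterval:
    id: str
    label: str
    members: tuple  # of ("stage"|"substage", name) pairs
    start_ma: float
    end_ma: float

    @property
    def duration_myr(self) -> float:
        return self.start_ma - self.end_ma

    def contains_age(self, age_ma: float) -> bool:
        """Membership under the half-open [end_ma, start_ma) convention."""
        return self.end_ma <= age_ma < self.start_ma


@dataclass
class Timescale:
    """Ordered (oldest first) contiguous stages plus substage spans."""

    stages: list[Stage]
    substages: list[SubstageSpan] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.stages = sorted(self.stages, key=lambda s: -s.start_ma)
        for a, b in zip(self.stages, self.stages[1:]):
            if abs(a.end_ma - b.start_ma) > _TOL:
                raise TimescaleError(
                    f"stages not contiguous: {a.name!r} ends at {a.end_ma} Ma "
                    f"but {b.name!r} starts at {b.start_ma} Ma"
                )
        names = [s.name for s in self.stages]
        if len(set(names)) != len(names):
            raise TimescaleError("duplicate stage names")
        self._stage_index = {s.name.lower(): s for s in self.stages}
        self._substage_index = {s.name.lower(): s for s in self.substages}

    # -- lookups ---------------------------------------------------------
    def stage(self, name: str) -> Stage:
        try:
            return self._stage_index[name.strip().lower()]
        except KeyError:
            raise TimescaleError(f"unknown stage {name!r}") from None

    def substage(self, name: str) -> SubstageSpan:
        try:
            return self._substage_index[name.strip().lower()]
        except KeyError:
            raise TimescaleError(f"unknown substage {name!r}") from None

    def has_stage(self, name: str) -> bool:
        return name.strip().lower() in self._stage_index

    def has_substage(self, name: str) -> bool:
        return name.strip().lower() in self._substage_index

    def span_of(self, kind: str, name: str) -> tuple[float, float]:
        """(start_ma, end_ma) of a named stage or substage."""
        if kind == "stage":
            s = self.stage(name)
        elif kind == "substage":
            s = self.substage(name)
        else:
            raise TimescaleError(f"unknown member kind {kind!r}")
        return (s.start_ma, s.end_ma)

    @property
    def start_ma(self) -> float:
        return self.stages[0].start_ma

    @property
    def end_ma(self) -> float:
        return self.stages[-1].end_ma


def _as_frame(source: TableSource) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source.copy()
    return pd.read_csv(source)


def load_timescale(stage_table: TableSource,
                   substage_table: TableSource | None = None) -> Timescale:
    """Build a validated :class:`Timescale` from tabular sources.

    ``stage_table`` needs columns name, period, start_ma, end_ma; rows may
    be in any order.  Gaps or overlaps between successive stages raise
    :class:`TimescaleError` naming the offending pair.
    """
    df = _as_frame(stage_table)
    required = {"name", "period", "start_ma", "end_ma"}
    missing = required - set(df.columns)
    if missing:
        raise TimescaleError(f"stage table missing columns {sorted(missing)}")
    stages = [
        Stage(str(r["name"]).strip(), str(r["period"]).strip(),
              float(r["start_ma"]), float(r["end_ma"]))
        for r in df.to_dict("records")
    ]
    substages: list[SubstageSpan] = []
    if substage_table is not None:
        sdf = _as_frame(substage_table)
        substages = [
            SubstageSpan(str(r["name"]).strip(), str(r["parent_stage"]).strip(),
                         float(r["start_ma"]), float(r["end_ma"]))
            for r in sdf.to_dict("records")
        ]
    return Timescale(stages=stages, substages=substages)


def _data_path(name: str):
    return resources.files("palaeodiv.data").joinpath(name)


def load_default_timescale() -> Timescale:
    """The packaged ICS stage table (v2021 boundary ages) with substages."""
    with resources.as_file(_data_path("ics_stages.csv")) as p_st, \
            resources.as_file(_data_path("substages.csv")) as p_ss:
        return load_timescale(p_st, p_ss)


def load_scheme(source: TableSource) -> pd.DataFrame:
    """Read an interval-scheme table (composite_id,label,member_kind,member_name)."""
    df = _as_frame(source)
    required = {"composite_id", "label", "member_kind", "member_name"}
    missing = required - set(df.columns)
    if missing:
        raise TimescaleError(f"scheme table missing columns {sorted(missing)}")
    return df


def build_composite_intervals(ts: Timescale,
                              scheme: TableSource) -> list[CompositeInterval]:
    """Assemble ordered, gap-free composite intervals from a scheme table.

    Each composite's members (stages and/or substages) must tile a single
    contiguous age span; composites must not overlap one another.
    """
    df = load_scheme(scheme)
    intervals: list[CompositeInterval] = []
    for cid in df["composite_id"].drop_duplicates():
        rows = df[df["composite_id"] == cid]
        label = str(rows["label"].iloc[0])
        members = tuple(
            (str(k).strip(), str(n).strip())
            for k, n in zip(rows["member_kind"], rows["member_name"])
        )
        spans = sorted((ts.span_of(k, n) for k, n in members),
                       key=lambda s: -s[0])
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if abs(e1 - s2) > _TOL:
                raise TimescaleError(
                    f"composite {cid!r}: member spans not contiguous "
                    f"({e1} Ma vs {s2} Ma)"
                )
        intervals.append(CompositeInterval(
            id=str(cid), label=label, members=members,
            start_ma=spans[0][0], end_ma=spans[-1][1],
        ))
    intervals.sort(key=lambda iv: -iv.start_ma)
    for a, b in zip(intervals, intervals[1:]):
        if b.start_ma - a.end_ma > _TOL:
            raise TimescaleError(
                f"composites {a.id!r} and {b.id!r} overlap "
                f"({a.end_ma} Ma vs {b.start_ma} Ma)"
            )
        if a.end_ma - b.start_ma > _TOL:
            raise TimescaleError(
                f"gap between composites {a.id!r} and {b.id!r} "
                f"({a.end_ma} Ma vs {b.start_ma} Ma)"
            )
    return intervals


def load_default_scheme(ts: Timescale | None = None) -> list[CompositeInterval]:
    """The packaged ~9 Myr equal-length composite scheme (20 bins)."""
    ts = ts or load_default_timescale()
    with resources.as_file(_data_path("equal_length_scheme.csv")) as p:
        return build_composite_intervals(ts, p)


def stage_identity_scheme(ts: Timescale) -> list[CompositeInterval]:
    """One composite per ICS stage (the unmerged comparison scheme)."""
    return [
        CompositeInterval(id=s.name, label=s.name,
                          members=(("stage", s.name),),
                          start_ma=s.start_ma, end_ma=s.end_ma)
        for s in ts.stages
    ]


def write_scheme(intervals: Iterable[CompositeInterval],
                 path: str | Path) -> None:
    """Serialise a scheme back to its CSV form (round-trippable)."""
    rows = []
    for iv in intervals:
        for kind, name in iv.members:
            rows.append({"composite_id": iv.id, "label": iv.label,
                         "member_kind": kind, "member_name": name})
    pd.DataFrame(rows).to_csv(path, index=False)


def intervals_frame(intervals: Sequence[CompositeInterval]) -> pd.DataFrame:
    """Tidy view: one row per interval with bounds and duration."""
    return pd.DataFrame({
        "interval_id": [iv.id for iv in intervals],
        "label": [iv.label for iv in intervals],
        "start_ma": [iv.start_ma for iv in intervals],
        "end_ma": [iv.end_ma for iv in intervals],
        "duration_myr": [iv.duration_myr for iv in intervals],
    })
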