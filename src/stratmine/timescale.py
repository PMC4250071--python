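"""Geologic time intervals, their containment hierarchy, and analysis bins.

The geologic timescale is a rooted hierarchy of named intervals (eon > era >
period > epoch > stage), each with an old and a young boundary age in Ma
(millions of years before present).  Containment along the hierarchy —
"the Carboniferous contains the Namurian" — is what lets an age stated at a
coarse rank support or imply an age stated at a finer rank, and is used both
by the hierarchy factors of the extraction model and by the temporal
resolution filters of the diversity analysis.

An interval covers the half-open span ``[t_young, t_old)`` in Ma; analysis
bins follow the same convention, so a point age lying exactly on a shared
boundary belongs to the younger bin.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "RANKS",
    "GeologicInterval",
    "Bin",
    "IntervalTable",
    "load_interval_table",
    "default_interval_table",
    "interval_contains",
    "interval_midpoint",
]

#: Ranks ordered coarse to fine.
RANKS = ("eon", "era", "period", "epoch", "stage")

_RANK_ORDER = {r: i for i, r in enumerate(RANKS)}


class TimescaleError(ValueError):
    """Raised when an interval table violates its structural invariants."""


@dataclass(frozen=True)
class GeologicInterval:
    """A named interval of geologic time.

    Parameters
    ----------
    name : str
        Unique interval name, e.g. ``"Namurian"``.
    rank : str
        One of :data:`RANKS`.
    parent : str or None
        Name of the containing interval; ``None`` only for the root.
    t_old, t_young : float
        Boundary ages in Ma, ``t_old > t_young >= 0``.
    """

    name: str
    rank: str
    parent: str | None
    t_old: float
    t_young: float

    def __post_init__(self) -> None:
        if self.rank not in _RANK_ORDER:
            raise TimescaleError(f"{self.name}: unknown rank {self.rank!r}")
        # t_old == t_young is tolerated for degenerate point horizons
        # (their midpoint is the boundary age itself).
        if not (self.t_old >= self.t_young >= 0):
            raise TimescaleError(
                f"{self.name}: require t_old >= t_young >= 0, got "
                f"({self.t_old}, {self.t_young})"
            )

    @property
    def duration(self) -> float:
        return self.t_old - self.t_young

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.t_old + self.t_young)


@dataclass(frozen=True)
class Bin:
    """One analysis time bin, covering ``[t_young, t_old)`` Ma."""

    name: str
    t_old: float
    t_young: float

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.t_old + self.t_young)

    @property
    def duration(self) -> float:
        return self.t_old - self.t_young


@dataclass
class IntervalTable:
    """A validated interval hierarchy plus an ordered list of analysis bins.

    Bins are ordered old → young, index 0 being the oldest; they tile the
    total time span contiguously with no gaps or overlaps.
    """

    intervals: dict[str, GeologicInterval]
    bins: list[Bin] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._validate()

    # -- validation -------------------------------------------------------
    def _validate(self) -> None:
        roots = [iv for iv in self.intervals.values() if iv.parent is None]
        if len(roots) != 1:
            raise TimescaleError(
                f"expected exactly one root interval, found "
                f"{sorted(iv.name for iv in roots)}"
            )
        for iv in self.intervals.values():
            if iv.parent is None:
                continue
            par = self.intervals.get(iv.parent)
            if par is None:
                raise TimescaleError(f"{iv.name}: unknown parent {iv.parent!r}")
            if _RANK_ORDER[iv.rank] <= _RANK_ORDER[par.rank]:
                raise TimescaleError(
                    f"{iv.name} ({iv.rank}) does not refine parent "
                    f"{par.name} ({par.rank})"
                )
            if iv.t_old > par.t_old or iv.t_young < par.t_young:
                raise TimescaleError(
                    f"containment violation: {iv.name} "
                    f"[{iv.t_young}, {iv.t_old}] extends beyond parent "
                    f"{par.name} [{par.t_young}, {par.t_old}]"
                )
        if self.bins:
            for older, younger in zip(self.bins, self.bins[1:]):
                if older.t_old <= older.t_young or younger.t_old <= younger.t_young:
                    raise TimescaleError("bins must have positive duration")
                if abs(older.t_young - younger.t_old) > 1e-9:
                    raise TimescaleError(
                        f"bins {older.name!r} and {younger.name!r} are not "
                        f"contiguous ({older.t_young} vs {younger.t_old})"
                    )

    # -- lookups ----------------------------------------------------------
    def __contains__(self, name: str) -> bool:
        return name in self.intervals

    def get(self, name: str) -> GeologicInterval:
        try:
            return self.intervals[name]
        except KeyError:
            raise KeyError(f"unknown interval {name!r}") from None

    def ancestors(self, name: str) -> list[str]:
        """Names of the strict ancestors of *name*, nearest first."""
        out: list[str] = []
        cur = self.get(name).parent
        while cur is not None:
            out.append(cur)
            cur = self.get(cur).parent
        return out

    def contains(self, a: str, b: str) -> bool:
        """True iff interval *a* equals *b* or is an ancestor of *b*."""
        if a == b:
            self.get(a)
            return True
        self.get(a)
        return a in self.ancestors(b)

    def related(self, a: str, b: str) -> bool:
        """True iff one of *a*, *b* contains the other."""
        return self.contains(a, b) or self.contains(b, a)

    def midpoint(self, name: str) -> float:
        return self.get(name).midpoint

    # -- bins -------------------------------------------------------------
    def bin_index(self, name: str) -> int:
        for i, b in enumerate(self.bins):
            if b.name == name:
                return i
        raise KeyError(f"unknown bin {name!r}")

    def bins_overlapping(self, name: str) -> list[int]:
        """Indices of analysis bins whose span intersects interval *name*.

        Intersection is on the half-open spans, so an interval touching a
        bin only at a boundary point does not overlap it; a zero-length
        point age falls in the younger of the two bins sharing its boundary.
        """
        iv = self.get(name)
        out = []
        if iv.t_old == iv.t_young:
            # point horizon: a shared boundary age belongs to the younger
            # bin; an age of exactly 0 falls in the youngest bin
            p = iv.t_old
            for i, b in enumerate(self.bins):
                if b.t_young < p <= b.t_old or (p == 0 and b.t_young == 0):
                    out.append(i)
                    break
            return out
        for i, b in enumerate(self.bins):
            if iv.t_old > b.t_young and iv.t_young < b.t_old:
                out.append(i)
        return out


def _parse_age(value: str, row: int, col: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise TimescaleError(f"row {row}: malformed {col} value {value!r}") from None


def load_interval_table(
    path: str | Path,
    bin_rank: str = "epoch",
    bins_path: str | Path | None = None,
) -> IntervalTable:
    """Load an interval hierarchy from CSV and derive analysis bins.

    Parameters
    ----------
    path : path
        CSV with columns ``name,rank,parent,t_old,t_young``; an empty
        ``parent`` marks the root.
    bin_rank : str
        Rank whose intervals become the default analysis bins (they must
        tile the root span contiguously).
    bins_path : path, optional
        CSV with columns ``name,t_old,t_young`` overriding the derived
        bins, e.g. an explicit 52-bin scheme.
    """
    intervals: dict[str, GeologicInterval] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"name", "rank", "parent", "t_old", "t_young"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise TimescaleError(f"{path}: missing columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            name = row["name"].strip()
            if name in intervals:
                raise TimescaleError(f"row {lineno}: duplicate interval {name!r}")
            intervals[name] = GeologicInterval(
                name=name,
                rank=row["rank"].strip(),
                parent=row["parent"].strip() or None,
                t_old=_parse_age(row["t_old"], lineno, "t_old"),
                t_young=_parse_age(row["t_young"], lineno, "t_young"),
            )

    if bins_path is not None:
        bins = _read_bins(bins_path)
    else:
        spans = sorted(
            (iv for iv in intervals.values() if iv.rank == bin_rank),
            key=lambda iv: -iv.t_old,
        )
        # Regional intervals may overlap the global scheme; bins are built
        # from the contiguous chain only.
        bins = []
        for iv in spans:
            if bins and abs(bins[-1].t_young - iv.t_old) > 1e-9:
                continue
            bins.append(Bin(iv.name, iv.t_old, iv.t_young))
    return IntervalTable(intervals=intervals, bins=bins)


def _read_bins(path: str | Path) -> list[Bin]:
    bins: list[Bin] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            bins.append(
                Bin(
                    row["name"].strip(),
                    _parse_age(row["t_old"], lineno, "t_old"),
                    _parse_age(row["t_young"], lineno, "t_young"),
                )
            )
    bins.sort(key=lambda b: -b.t_old)
    return bins


def default_interval_table(bins_path: str | Path | None = None) -> IntervalTable:
    """The packaged ICS-like Phanerozoic table, epoch-level bins by default."""
    ref = resources.files("stratmine.data") / "intervals.csv"
    with resources.as_file(ref) as p:
        return load_interval_table(p, bins_path=bins_path)


# Thin functional aliases matching the operational surface. --------------------

def interval_contains(a: str, b: str, table: IntervalTable) -> bool:
    """True iff interval *b* equals *a* or descends from *a* in *table*."""
    return table.contains(a, b)


def interval_midpoint(a: str, table: IntervalTable) -> float:
    """Midpoint age ``(t_old + t_young)/2`` of interval *a* in Ma."""
    return table.midpoint(a)
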