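"""Taxonomy resolution, genus ranges, diversity, and turnover statistics.

The validation layer: both the machine-built and any reference occurrence
database are reduced with the same algorithms to a working taxonomy, genus
stratigraphic ranges under the range-through assumption, per-bin boundary
crosser counts, and the per-capita, per-interval origination and extinction
rates

    p_i = -ln(N_bt / N_t),    q_i = -ln(N_bt / N_b),

where N_bt counts genera crossing both boundaries of bin *i*, N_t those
crossing the top, and N_b those crossing the bottom.  Agreement between two
databases is summarized by Spearman rank correlations of first-differenced
(detrended) time series, and by per-genus first/last occurrence offsets in
Myr.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .kb import KBTuple
from .probkb import OccurrenceRecord
from .timescale import IntervalTable

__all__ = [
    "Taxonomy",
    "GenusRange",
    "DiversityCounts",
    "resolve_taxonomy",
    "apply_taxonomy",
    "genus_ranges",
    "rangethrough_diversity",
    "foote_rates",
    "range_offsets",
    "first_difference_spearman",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# taxonomy
# --------------------------------------------------------------------------

@dataclass
class Taxonomy:
    """Resolved synonymy and parent links."""

    senior_of: dict[str, str] = field(default_factory=dict)   # junior -> senior (one hop)
    parent_of: dict[str, str] = field(default_factory=dict)   # child -> parent
    dropped_opinions: list[KBTuple] = field(default_factory=list)

    def senior(self, name: str) -> str:
        """Resolve a name through synonym links to its terminal senior name."""
        cur = name
        seen = {cur}
        while cur in self.senior_of:
            cur = self.senior_of[cur]
            if cur in seen:  # defensive; cycles are broken during resolution
                break
            seen.add(cur)
        return cur


def _governing_object(opinions: list[KBTuple]) -> str:
    """Most recent opinion wins; ties by majority, then smallest name."""
    stats: dict[str, list] = {}
    for t in opinions:
        year = t.pub_year if t.pub_year is not None else -1
        rec = stats.setdefault(t.object, [year, 0])
        rec[0] = max(rec[0], year)
        rec[1] += 1
    return min(stats, key=lambda o: (-stats[o][0], -stats[o][1], o))


def resolve_taxonomy(opinions: Iterable[KBTuple]) -> Taxonomy:
    """Reduce raw opinion tuples to one governing opinion per name.

    Synonym cycles (A syn B, B syn A) are broken by dropping the most
    recently published cycle-closing opinion; degeneracies are logged,
    never fatal.
    """
    by_subject_syn: dict[str, list[KBTuple]] = {}
    by_subject_par: dict[str, list[KBTuple]] = {}
    for t in opinions:
        if t.relation == "opinion_synonym":
            by_subject_syn.setdefault(t.subject, []).append(t)
        elif t.relation == "opinion_belongs":
            by_subject_par.setdefault(t.subject, []).append(t)

    tax = Taxonomy()
    for child, ts in by_subject_par.items():
        tax.parent_of[child] = _governing_object(ts)

    senior_of = {s: _governing_object(ts) for s, ts in by_subject_syn.items()}

    # break synonym cycles deterministically
    while True:
        cycle = _find_cycle(senior_of)
        if cycle is None:
            break
        # drop the most recent opinion among the cycle edges; ties by subject
        def edge_key(subj: str):
            years = [
                t.pub_year if t.pub_year is not None else -1
                for t in by_subject_syn[subj]
                if t.object == senior_of[subj]
            ]
            return (max(years) if years else -1, subj)

        victim = max(cycle, key=edge_key)
        dropped = [
            t for t in by_subject_syn[victim] if t.object == senior_of[victim]
        ]
        tax.dropped_opinions.extend(dropped)
        logger.warning(
            "synonym cycle %s broken by dropping %s -> %s",
            "->".join(cycle + [cycle[0]]), victim, senior_of[victim],
        )
        del senior_of[victim]

    tax.senior_of = senior_of
    return tax


def _find_cycle(mapping: Mapping[str, str]) -> list[str] | None:
    colors: dict[str, int] = {}
    for start in sorted(mapping):
        if colors.get(start):
            continue
        path = []
        cur = start
        while cur in mapping and colors.get(cur, 0) != 2:
            if colors.get(cur) == 1:  # found a node on the current path
                return path[path.index(cur):]
            colors[cur] = 1
            path.append(cur)
            cur = mapping[cur]
        for node in path:
            colors[node] = 2
    return None


def apply_taxonomy(
    occurrences: Iterable[OccurrenceRecord], taxonomy: Taxonomy
) -> list[OccurrenceRecord]:
    """Re-key occurrence genera to their senior names."""
    out = []
    for o in occurrences:
        senior = taxonomy.senior(o.genus)
        if senior == o.genus:
            out.append(o)
        else:
            out.append(
                OccurrenceRecord(
                    senior, o.species, o.formation, o.interval, o.location,
                    o.doc_id, o.probability,
                )
            )
    return out


# --------------------------------------------------------------------------
# ranges and diversity
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GenusRange:
    """First and last occupied analysis bins of one genus (old -> young)."""

    genus: str
    first_bin: int
    last_bin: int
    first_age: float   # bin midpoint, Ma
    last_age: float

    def __post_init__(self) -> None:
        if self.first_bin > self.last_bin:
            raise ValueError(f"{self.genus}: first_bin > last_bin")


def genus_ranges(
    occurrences: Iterable[OccurrenceRecord], table: IntervalTable
) -> tuple[list[GenusRange], int]:
    """Per-genus first/last bins from single-bin occurrences.

    Occurrences whose stated interval overlaps more than one analysis bin
    are too coarse to place and are dropped (their count is returned and
    logged); the range-through assumption then fills every bin between the
    first and last occupied bins.
    """
    bins_of_interval: dict[str, list[int]] = {}
    occupied: dict[str, set[int]] = {}
    n_dropped = 0
    for o in occurrences:
        if o.interval not in bins_of_interval:
            bins_of_interval[o.interval] = table.bins_overlapping(o.interval)
        hit = bins_of_interval[o.interval]
        if len(hit) != 1:
            n_dropped += 1
            continue
        occupied.setdefault(o.genus, set()).add(hit[0])
    if n_dropped:
        logger.info("genus_ranges: dropped %d multi-bin occurrences", n_dropped)
    ranges = []
    for genus in sorted(occupied):
        first, last = min(occupied[genus]), max(occupied[genus])
        ranges.append(
            GenusRange(
                genus, first, last,
                table.bins[first].midpoint, table.bins[last].midpoint,
            )
        )
    return ranges, n_dropped


def rangethrough_diversity(ranges: Sequence[GenusRange], n_bins: int) -> np.ndarray:
    """diversity(i) = number of genera ranging through bin i."""
    div = np.zeros(n_bins, dtype=np.int64)
    for r in ranges:
        div[r.first_bin:r.last_bin + 1] += 1
    return div


@dataclass
class DiversityCounts:
    """Boundary-crosser bookkeeping and per-capita, per-interval rates.

    Per bin *i* (bins old -> young): ``N_bt`` cross both boundaries,
    ``N_bL`` cross the bottom and end within, ``N_Ft`` start within and
    cross the top, ``N_FL`` are confined singletons.  Rates are per
    interval (not divided by duration) unless durations are supplied.
    """

    N_bt: np.ndarray
    N_bL: np.ndarray
    N_Ft: np.ndarray
    N_FL: np.ndarray
    p_rate: np.ndarray
    q_rate: np.ndarray

    @property
    def N_b(self) -> np.ndarray:
        return self.N_bt + self.N_bL

    @property
    def N_t(self) -> np.ndarray:
        return self.N_bt + self.N_Ft

    @property
    def diversity(self) -> np.ndarray:
        return self.N_bt + self.N_bL + self.N_Ft + self.N_FL

    def to_dataframe(self, table: IntervalTable | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "N_bt": self.N_bt, "N_bL": self.N_bL,
                "N_Ft": self.N_Ft, "N_FL": self.N_FL,
                "diversity": self.diversity,
                "p_rate": self.p_rate, "q_rate": self.q_rate,
            }
        )
        if table is not None and len(table.bins) == len(df):
            df.insert(0, "bin", [b.name for b in table.bins])
        return df


def foote_rates(
    ranges: Sequence[GenusRange],
    n_bins: int,
    durations: Sequence[float] | None = None,
) -> DiversityCounts:
    """Boundary-crosser counts and per-capita origination/extinction rates.

    ``p = -ln(N_bt/N_t)`` and ``q = -ln(N_bt/N_b)``; a rate is NaN where
    its denominator or N_bt is zero.  Passing per-bin ``durations`` (Myr)
    converts the per-interval rates to per-Myr rates.
    """
    N_bt = np.zeros(n_bins, dtype=np.int64)
    N_bL = np.zeros(n_bins, dtype=np.int64)
    N_Ft = np.zeros(n_bins, dtype=np.int64)
    N_FL = np.zeros(n_bins, dtype=np.int64)
    for r in ranges:
        for i in range(r.first_bin, r.last_bin + 1):
            bottom = r.first_bin < i
            top = r.last_bin > i
            if bottom and top:
                N_bt[i] += 1
            elif bottom:
                N_bL[i] += 1
            elif top:
                N_Ft[i] += 1
            else:
                N_FL[i] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        N_t = N_bt + N_Ft
        N_b = N_bt + N_bL
        p = -np.log(N_bt / np.where(N_t > 0, N_t, 1))
        q = -np.log(N_bt / np.where(N_b > 0, N_b, 1))
    p[(N_bt == 0) | (N_t == 0)] = np.nan
    q[(N_bt == 0) | (N_b == 0)] = np.nan
    if durations is not None:
        d = np.asarray(durations, dtype=float)
        p = p / d
        q = q / d
    return DiversityCounts(N_bt, N_bL, N_Ft, N_FL, p, q)


# --------------------------------------------------------------------------
# cross-database comparison
# --------------------------------------------------------------------------

def range_offsets(
    ranges_a: Sequence[GenusRange],
    ranges_b: Sequence[GenusRange],
    sign: str = "a_minus_b",
) -> pd.DataFrame:
    """Per-genus first/last occurrence offsets in Myr, for shared genera.

    Ages are bin midpoints in Ma; the default sign convention reports
    (age in a) − (age in b), so a positive last-occurrence offset means
    database *a* extends the genus to an older last occurrence.
    """
    if sign not in ("a_minus_b", "b_minus_a"):
        raise ValueError(f"unknown sign convention {sign!r}")
    s = 1.0 if sign == "a_minus_b" else -1.0
    a_by = {r.genus: r for r in ranges_a}
    rows = []
    for rb in ranges_b:
        ra = a_by.get(rb.genus)
        if ra is None:
            continue
        rows.append(
            {
                "genus": rb.genus,
                "first_offset_myr": s * (ra.first_age - rb.first_age),
                "last_offset_myr": s * (ra.last_age - rb.last_age),
            }
        )
    return pd.DataFrame(rows, columns=["genus", "first_offset_myr", "last_offset_myr"])


def first_difference_spearman(
    series_a: Sequence[float], series_b: Sequence[float]
) -> tuple[float, float]:
    """Spearman correlation of first-differenced (detrended) time series.

    Differences are taken between consecutive bins where both series are
    defined at both endpoints; at least 3 difference pairs are required.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    use = ok[1:] & ok[:-1]
    da = (a[1:] - a[:-1])[use]
    db = (b[1:] - b[:-1])[use]
    if len(da) < 3:
        raise ValueError(f"only {len(da)} usable first differences (need >= 3)")
    import warnings

    with warnings.catch_warnings():
        # a constant difference series has no defined correlation; NaN is
        # the right answer and callers treat it as such
        warnings.simplefilter("ignore", scipy.stats.ConstantInputWarning)
        rho, p = scipy.stats.spearmanr(da, db)
    return float(rho), float(p)
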