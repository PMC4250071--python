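"""Assembly of the probabilistic occurrence database.

Entity-level marginals become tuples with probabilities; tuples above the
acceptance threshold (0.95 by default — the probability cut under which
every published extraction is reported) are combined into occurrence
records.  Two editorial rules shape the output:

* **best age** — for each geological unit the accepted age statements from
  all documents are reduced to the most precise (shortest duration) and,
  among equally precise ones, the most recently published age;
* **formal units only** — a taxon mentioned in a document that links it to
  no recognized geological unit yields no occurrence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .graph import FactorGraph
from .inference import MarginalTable
from .kb import KBTuple
from .timescale import IntervalTable, RANKS

__all__ = [
    "OccurrenceRecord",
    "entity_tuples",
    "filter_by_probability",
    "infer_unit_age",
    "assemble_occurrences",
    "resolution_filter",
    "export_occurrences",
    "read_occurrences",
    "export_opinions",
]


@dataclass(frozen=True)
class OccurrenceRecord:
    """A taxon in a formation with age, place, source, and probability."""

    genus: str
    species: str | None
    formation: str
    interval: str
    location: str
    doc_id: str
    probability: float


def entity_tuples(graph: FactorGraph, marginals: MarginalTable) -> list[KBTuple]:
    """Entity-layer variables as KB tuples with marginal probabilities.

    Provenance: ``doc_id`` is the lexicographically first contributing
    document; ``pub_year`` the most recent year among contributing
    documents (feeding the recency tie-break of the best-age rule).
    """
    mentions_of: dict[str, list[str]] = {}
    for f in graph.factors:
        if f.kind == "aggregation":
            mentions_of.setdefault(f.variable_ids[0], []).extend(f.variable_ids[1:])
    out: list[KBTuple] = []
    for v in graph.entity_variables():
        rel, subj, obj = v.payload
        docs = [
            graph.variables[mid].payload.subject.doc_id
            for mid in mentions_of.get(v.id, [])
        ]
        years = [
            y for y in (_doc_year(graph, d) for d in docs) if y is not None
        ]
        out.append(
            KBTuple(
                relation=rel,
                subject=subj,
                object=obj,
                doc_id=min(docs) if docs else None,
                pub_year=max(years) if years else None,
                probability=marginals.probabilities.get(v.id),
            )
        )
    out.sort(key=lambda t: t.key())
    return out


def _doc_year(graph: FactorGraph, doc_id: str) -> int | None:
    # candidate payloads do not carry the year; the pipeline attaches a
    # doc_id -> pub_year map on the graph when it builds it
    years = getattr(graph, "doc_years", None)
    if years:
        return years.get(doc_id)
    return None


def filter_by_probability(tuples: Iterable[KBTuple], tau: float) -> list[KBTuple]:
    """Keep tuples with probability >= tau; tau must lie in [0, 1]."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must be in [0, 1], got {tau}")
    return [t for t in tuples if t.probability is not None and t.probability >= tau]


def infer_unit_age(
    tuples: Sequence[KBTuple], table: IntervalTable
) -> str:
    """The most precise, most recently published age among accepted tuples.

    Precision is interval duration in Myr (shorter = more precise); ties
    break by publication year (more recent wins), then probability, then
    name.  All tuples must be ``formation_age`` rows for one formation.
    """
    if not tuples:
        raise ValueError("no accepted age tuples")

    def sort_key(t: KBTuple):
        iv = table.get(t.object)
        year = t.pub_year if t.pub_year is not None else -1
        prob = t.probability if t.probability is not None else 0.0
        return (iv.duration, -year, -prob, t.object)

    return min(tuples, key=sort_key).object


def assemble_occurrences(
    accepted: Iterable[KBTuple], table: IntervalTable
) -> list[OccurrenceRecord]:
    """Occurrence records from thresholded tuples.

    A ``taxon_in_formation`` tuple becomes a record only if its formation
    also has at least one accepted age (the formal-unit rule: taxa without
    a dated, recognized unit yield nothing).  Ages are unit-level inferred
    ages, not per-document statements; locations take the highest-
    probability accepted location per formation.
    """
    by_rel: dict[str, list[KBTuple]] = {}
    for t in accepted:
        by_rel.setdefault(t.relation, []).append(t)

    ages: dict[str, list[KBTuple]] = {}
    for t in by_rel.get("formation_age", []):
        if t.object in table:
            ages.setdefault(t.subject, []).append(t)
    unit_age = {f: infer_unit_age(ts, table) for f, ts in ages.items()}

    locs: dict[str, str] = {}
    for t in sorted(
        by_rel.get("formation_location", []),
        key=lambda t: (-(t.probability or 0.0), t.object),
    ):
        locs.setdefault(t.subject, t.object)

    out: list[OccurrenceRecord] = []
    for t in sorted(by_rel.get("taxon_in_formation", []), key=lambda t: t.key()):
        if t.object not in unit_age:
            continue
        parts = t.subject.split()
        genus = parts[0]
        species = t.subject if len(parts) > 1 else None
        out.append(
            OccurrenceRecord(
                genus=genus,
                species=species,
                formation=t.object,
                interval=unit_age[t.object],
                location=locs.get(t.object, ""),
                doc_id=t.doc_id or "",
                probability=t.probability if t.probability is not None else 1.0,
            )
        )
    return out


def resolution_filter(
    occurrences: Iterable[OccurrenceRecord],
    table: IntervalTable,
    min_rank: str = "epoch",
) -> list[OccurrenceRecord]:
    """Keep occurrences dated at ``min_rank`` or finer temporal resolution."""
    if min_rank not in RANKS:
        raise ValueError(f"unknown rank {min_rank!r}")
    cut = RANKS.index(min_rank)
    out = []
    for occ in occurrences:
        iv = table.get(occ.interval)
        if RANKS.index(iv.rank) >= cut:
            out.append(occ)
    return out


_OCC_HEADER = [
    "genus", "species", "formation", "interval", "location", "doc_id", "probability",
]


def _fmt_prob(p: float) -> str:
    """At least 4 decimal places, without losing precision."""
    s = f"{p:.4f}"
    return s if float(s) == p else repr(p)


def export_occurrences(
    occurrences: Iterable[OccurrenceRecord], path: str | Path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_OCC_HEADER)
        for o in occurrences:
            w.writerow(
                [o.genus, o.species or "", o.formation, o.interval, o.location,
                 o.doc_id, _fmt_prob(o.probability)]
            )


def read_occurrences(
    path: str | Path, colmap: Mapping[str, str] | None = None
) -> list[OccurrenceRecord]:
    """Read an occurrence CSV; ``colmap`` maps our field names to the
    column names of a foreign file with a different schema."""
    colmap = dict(colmap or {})
    out: list[OccurrenceRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            get = lambda k, default="": row.get(colmap.get(k, k), default)
            out.append(
                OccurrenceRecord(
                    genus=get("genus"),
                    species=get("species") or None,
                    formation=get("formation"),
                    interval=get("interval"),
                    location=get("location"),
                    doc_id=get("doc_id"),
                    probability=float(get("probability") or 1.0),
                )
            )
    return out


def export_opinions(tuples: Iterable[KBTuple], path: str | Path) -> None:
    """Opinion tuples (belongs / synonym) as a KB CSV."""
    from .kb import write_kb

    write_kb(
        [t for t in tuples if t.relation in ("opinion_belongs", "opinion_synonym")],
        path,
    )
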