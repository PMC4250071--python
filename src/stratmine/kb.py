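"""Knowledge-base tuples and their CSV serialization.

A :class:`KBTuple` is a single subject–relation–object assertion — the unit
of both seed knowledge (distant supervision input) and machine output.  Seed
tuples carry no probability; machine-extracted tuples carry the marginal
probability estimated for them, plus document and publication-year
provenance where known.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = ["RELATIONS", "KBTuple", "read_kb", "write_kb", "KBFormatError"]

#: Relations the extractor understands.
RELATIONS = (
    "formation_age",        # formation -> geologic interval
    "formation_location",   # formation -> place name
    "taxon_in_formation",   # taxon -> formation (a fossil occurrence)
    "opinion_belongs",      # child taxon -> parent taxon
    "opinion_synonym",      # junior name -> senior name
)


class KBFormatError(ValueError):
    """Malformed KB file (unknown relation, bad row)."""


@dataclass(frozen=True, order=True)
class KBTuple:
    relation: str
    subject: str
    object: str
    doc_id: str | None = None
    pub_year: int | None = None
    probability: float | None = None

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise KBFormatError(f"unknown relation {self.relation!r}")
        if self.probability is not None and not 0.0 <= self.probability <= 1.0:
            raise KBFormatError(f"probability out of range: {self.probability}")

    def key(self) -> tuple[str, str, str]:
        """The (relation, subject, object) identity of the assertion."""
        return (self.relation, self.subject, self.object)


_HEADER = ["relation", "subject", "object", "doc_id", "pub_year", "probability"]


def read_kb(path: str | Path) -> list[KBTuple]:
    """Read tuples from CSV; empty fields decode to ``None``."""
    out: list[KBTuple] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(_HEADER) <= set(reader.fieldnames):
            raise KBFormatError(f"{path}: expected header {','.join(_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append(
                    KBTuple(
                        relation=row["relation"],
                        subject=row["subject"],
                        object=row["object"],
                        doc_id=row["doc_id"] or None,
                        pub_year=int(row["pub_year"]) if row["pub_year"] else None,
                        probability=(
                            float(row["probability"]) if row["probability"] else None
                        ),
                    )
                )
            except (KBFormatError, ValueError, KeyError) as exc:
                raise KBFormatError(f"{path}, line {lineno}: {exc}") from exc
    return out


def write_kb(tuples: Iterable[KBTuple], path: str | Path) -> None:
    """Write tuples to CSV; ``read_kb(write_kb(t)) == t`` field for field."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for t in tuples:
            writer.writerow(
                [
                    t.relation,
                    t.subject,
                    t.object,
                    t.doc_id or "",
                    "" if t.pub_year is None else t.pub_year,
                    "" if t.probability is None else repr(t.probability),
                ]
            )
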