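"""Gazetteer-driven entity mention extraction and relation candidates.

Entity recognition is dictionary based: per-type gazetteers map surface
token sequences to canonical entity ids (with lithology variants such as
"Waldron Fm" for "Waldron Shale"), plus a binomial pattern that recognizes
``<KnownGenus> <lowercase epithet>`` species names that no dictionary lists.
Co-located mentions (same sentence, or same table row) become relation
candidates, each carrying a deterministic set of string features — the raw
material the factor graph ties weights over.

Spans are 0-based half-open token ranges throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .corpus import Document
from .kb import KBTuple

__all__ = [
    "Mention",
    "RelationCandidate",
    "build_gazetteers",
    "extract_mentions",
    "generate_candidates",
    "extract_features",
    "SUBJECT_TYPE",
    "OBJECT_TYPE",
]

#: relation -> (subject entity type, object entity type)
SUBJECT_TYPE = {
    "formation_age": "formation",
    "formation_location": "formation",
    "taxon_in_formation": "taxon",
    "opinion_belongs": "taxon",
    "opinion_synonym": "taxon",
}
OBJECT_TYPE = {
    "formation_age": "interval",
    "formation_location": "location",
    "taxon_in_formation": "formation",
    "opinion_belongs": "taxon",
    "opinion_synonym": "taxon",
}

_KB_ROLE_TYPES = {
    "formation_age": ("formation", "interval"),
    "formation_location": ("formation", "location"),
    "taxon_in_formation": ("taxon", "formation"),
    "opinion_belongs": ("taxon", "taxon"),
    "opinion_synonym": ("taxon", "taxon"),
}

_FORMATION_TRIGGERS = ("Formation", "Fm", "Shale", "Limestone", "Sandstone")

#: Gazetteer type: entity type -> surface token tuple -> sorted entity ids.
Gazetteers = dict[str, dict[tuple[str, ...], list[str]]]


@dataclass(frozen=True)
class Mention:
    """One recognized entity span in a document."""

    doc_id: str
    scope: str                 # "sentence" | "table"
    index: int                 # sentence index or table row
    col: int | None            # table column (None in sentences)
    start: int                 # token span within sentence/cell
    end: int
    entity_type: str
    surface: str
    entity_id: str
    ambiguous_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class RelationCandidate:
    """A possible relation between two co-located mentions."""

    relation: str
    subject: Mention
    object: Mention
    features: tuple[str, ...]
    variable_id: str


def _add_surface(gaz: Gazetteers, etype: str, surface: str, entity_id: str) -> None:
    toks = tuple(surface.split())
    if not toks:
        return
    bucket = gaz.setdefault(etype, {}).setdefault(toks, [])
    if entity_id not in bucket:
        bucket.append(entity_id)
        bucket.sort()


def build_gazetteers(
    seed_kb: Iterable[KBTuple],
    world_vocab: Mapping[str, Iterable[str]] | None = None,
) -> Gazetteers:
    """Surface-form dictionaries per entity type.

    ``world_vocab`` maps entity type to known names (the stand-in for the
    lexica — taxonomic name lists, stratigraphic lexicons, place-name
    gazetteers — the full-scale system draws on).  Formation entries also
    match with any lithology trigger suffix, so "Waldron Shale" is found
    when written "Waldron Fm".  Duplicate surface forms keep all candidate
    ids (sorted); resolution picks the first.
    """
    gaz: Gazetteers = {t: {} for t in ("taxon", "formation", "interval", "location")}

    def add(etype: str, name: str) -> None:
        _add_surface(gaz, etype, name, name)
        if etype == "formation":
            parts = name.split()
            if len(parts) >= 2 and parts[-1] in _FORMATION_TRIGGERS:
                base = " ".join(parts[:-1])
                for trig in _FORMATION_TRIGGERS:
                    _add_surface(gaz, etype, f"{base} {trig}", name)

    for t in seed_kb:
        s_type, o_type = _KB_ROLE_TYPES[t.relation]
        add(s_type, t.subject)
        add(o_type, t.object)
    if world_vocab:
        for etype, names in world_vocab.items():
            for name in names:
                add(etype, name)
    return gaz


def _match_sequence(
    tokens: Sequence[str], gaz_for_type: Mapping[tuple[str, ...], list[str]],
    max_len: int = 4,
) -> list[tuple[int, int, list[str]]]:
    """Longest-match, non-overlapping scan; ties broken leftmost."""
    out = []
    i = 0
    n = len(tokens)
    while i < n:
        hit = None
        for L in range(min(max_len, n - i), 0, -1):
            key = tuple(tokens[i:i + L])
            if key in gaz_for_type:
                hit = (i, i + L, gaz_for_type[key])
                break
        if hit:
            out.append(hit)
            i = hit[1]
        else:
            i += 1
    return out


_EPITHET_SUFFIXES = ("a", "us", "is", "um", "ans", "ens", "or", "ex")
_EPITHET_STOP = {"is", "was", "in", "of", "and", "the", "a", "here", "for"}


def _binomial_matches(
    tokens: Sequence[str], taxon_gaz: Mapping[tuple[str, ...], list[str]]
) -> list[tuple[int, int, list[str]]]:
    """``<KnownGenus> <epithet>`` species matches missing from the gazetteer."""
    out = []
    for i in range(len(tokens) - 1):
        genus, epi = tokens[i], tokens[i + 1]
        if (genus,) not in taxon_gaz:
            continue
        if (genus, epi) in taxon_gaz:
            continue  # plain gazetteer already covers it
        if not (epi.isalpha() and epi.islower()) or epi in _EPITHET_STOP:
            continue
        if not epi.endswith(_EPITHET_SUFFIXES):
            continue
        out.append((i, i + 2, [f"{genus} {epi}"]))
    return out


def extract_mentions(doc: Document, gazetteers: Gazetteers) -> list[Mention]:
    """All entity mentions in a document, deterministic order.

    Per entity type, spans are longest-match and non-overlapping.  Taxon
    matching additionally applies the binomial pattern; a binomial overlap
    supersedes a bare-genus gazetteer hit at the same position.
    """
    mentions: list[Mention] = []

    def scan(tokens: Sequence[str], scope: str, index: int, col: int | None) -> None:
        for etype, gaz_t in gazetteers.items():
            hits = _match_sequence(tokens, gaz_t)
            if etype == "taxon":
                bins = _binomial_matches(tokens, gaz_t)
                starts = {b[0] for b in bins}
                hits = [h for h in hits if h[0] not in starts] + bins
                hits.sort()
            for start, end, ids in hits:
                mentions.append(
                    Mention(
                        doc_id=doc.doc_id,
                        scope=scope,
                        index=index,
                        col=col,
                        start=start,
                        end=end,
                        entity_type=etype,
                        surface=" ".join(tokens[start:end]),
                        entity_id=ids[0],
                        ambiguous_ids=tuple(ids) if len(ids) > 1 else (),
                    )
                )

    for sidx, sent in enumerate(doc.sentences):
        scan(sent, "sentence", sidx, None)
    for row, colno, toks in doc.table_cells:
        scan(toks, "table", row, colno)
    mentions.sort(
        key=lambda m: (m.scope, m.index, m.col if m.col is not None else -1, m.start,
                       m.entity_type)
    )
    return mentions


def generate_candidates(
    mentions: Sequence[Mention], scope: str = "sentence"
) -> list[RelationCandidate]:
    """Type-compatible co-located mention pairs, in deterministic order.

    ``scope="sentence"`` pairs mentions within one sentence; ``"table_row"``
    pairs mentions within one table row (across cells).  For same-type
    relations (the two taxonomic opinions) the textually earlier mention is
    the subject, and one candidate per relation is produced.
    """
    groups: dict[tuple, list[Mention]] = {}
    for m in mentions:
        if scope == "sentence" and m.scope == "sentence":
            groups.setdefault((m.doc_id, m.index), []).append(m)
        elif scope == "table_row" and m.scope == "table":
            groups.setdefault((m.doc_id, m.index), []).append(m)

    out: list[RelationCandidate] = []
    for key in sorted(groups):
        ms = groups[key]
        ms.sort(key=lambda m: (m.col if m.col is not None else -1, m.start))
        for i, a in enumerate(ms):
            for b in ms[i + 1:]:
                for relation in SUBJECT_TYPE:
                    st, ot = SUBJECT_TYPE[relation], OBJECT_TYPE[relation]
                    if st == ot:
                        if a.entity_type == st and b.entity_type == ot and a is not b:
                            out.append(_make_candidate(relation, a, b))
                    elif a.entity_type == st and b.entity_type == ot:
                        out.append(_make_candidate(relation, a, b))
                    elif b.entity_type == st and a.entity_type == ot:
                        out.append(_make_candidate(relation, b, a))
    return out


def _make_candidate(relation: str, subj: Mention, obj: Mention) -> RelationCandidate:
    vid = (
        f"m::{subj.doc_id}::{subj.scope}{subj.index}"
        f"::{relation}::{subj.entity_id}::{obj.entity_id}"
        f"::{subj.col}:{subj.start}-{obj.col}:{obj.start}"
    )
    return RelationCandidate(
        relation=relation, subject=subj, object=obj, features=(), variable_id=vid
    )


def extract_features(cand: RelationCandidate, doc: Document) -> tuple[str, ...]:
    """Deterministic feature strings for a candidate.

    Sentence candidates get inter-mention token features, a bucketed token
    distance, mention order, and immediate context tokens; table candidates
    get a same-row flag and the column-header tokens.  Features are
    prefixed with the relation so weights never tie across relations.
    """
    r = cand.relation
    subj, obj = cand.subject, cand.object
    feats: list[str] = []
    if subj.scope == "table":
        feats.append(f"{r}::SAME_TABLE_ROW")
        headers = {
            (colno): toks
            for row, colno, toks in doc.table_cells
            if row == 0
        }
        for role, m in (("S", subj), ("O", obj)):
            hdr = headers.get(m.col)
            if hdr:
                feats.append(f"{r}::COLHDR_{role}={'_'.join(t.lower() for t in hdr)}")
    else:
        tokens = doc.sentences[subj.index]
        first, second = (subj, obj) if subj.start <= obj.start else (obj, subj)
        gap = tokens[first.end:second.start]
        for tok in gap:
            feats.append(f"{r}::BTW={tok.lower()}")
        dist = len(gap)
        feats.append(f"{r}::DIST={dist if dist < 3 else '3+'}")
        feats.append(f"{r}::{'SUBJ_FIRST' if first is subj else 'OBJ_FIRST'}")
        if first.start > 0:
            feats.append(f"{r}::PRE={tokens[first.start - 1].lower()}")
        if second.end < len(tokens):
            feats.append(f"{r}::POST={tokens[second.end].lower()}")
    # stable order, no duplicates
    seen: set[str] = set()
    uniq = [f for f in feats if not (f in seen or seen.add(f))]
    return tuple(uniq)


def extract_document(
    doc: Document, gazetteers: Gazetteers
) -> tuple[list[Mention], list[RelationCandidate]]:
    """Mentions plus fully featurized sentence and table-row candidates."""
    mentions = extract_mentions(doc, gazetteers)
    cands = generate_candidates(mentions, "sentence") + generate_candidates(
        mentions, "table_row"
    )
    out = []
    for c in cands:
        feats = extract_features(c, doc)
        out.append(
            RelationCandidate(c.relation, c.subject, c.object, feats, c.variable_id)
        )
    return mentions, out
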