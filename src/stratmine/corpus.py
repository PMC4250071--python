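"""Synthetic literature generator: a gold world rendered as noisy documents.

The generator plays the role of the digitized literature plus the OCR/NLP
front end: it invents a consistent world of geological formations (each with
one true age, one location, and a fauna of genera), a taxonomy with
belongs-to chains and junior synonyms, renders every fact through templated
sentences or table rows into dated documents, and finally splits off a
partial seed knowledge base that stands in for a human-built database used
for distant supervision.

Noise knobs emulate the failure modes of real machine reading:

* ``corruption_rate`` — character-level token corruption (OCR damage);
* ``distractor_rate`` — sentences that mention entities without asserting a
  relation ("the X Formation is older than the Silurian"), which the
  extractor must learn to reject;
* ambiguous ("weak") templates used both for true facts and for false
  pairings, so that some candidates are genuinely uncertain;
* ``synonym_usage_rate`` — occurrences written under a junior synonym while
  the gold record is keyed to the senior name;
* ``coarse_age_rate`` — age statements at a coarser rank than the true age
  (the Carboniferous instead of the Serpukhovian).

Everything is drawn from a single seeded generator, so a world is
bit-for-bit reproducible from its configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .kb import KBTuple
from .timescale import IntervalTable

__all__ = [
    "WorldConfig",
    "Document",
    "MentionAnnotation",
    "SentenceFact",
    "GoldWorld",
    "generate_world",
    "corrupt_tokens",
    "split_seed_kb",
    "write_corpus",
    "read_corpus",
]


# --------------------------------------------------------------------------
# configuration and record types
# --------------------------------------------------------------------------

@dataclass
class WorldConfig:
    """Knobs of the synthetic world; all randomness flows from ``rng_seed``."""

    n_formations: int = 30
    n_taxa: int = 120
    n_documents: int = 100
    corruption_rate: float = 0.0
    distractor_rate: float = 0.3
    synonym_usage_rate: float = 0.2
    coarse_age_rate: float = 0.25
    ambiguous_rate: float = 0.15
    table_fraction: float = 0.3
    synonym_fraction: float = 0.1
    species_fraction: float = 0.3
    mean_mentions: float = 2.0
    seed_kb_fraction: float = 0.5
    rng_seed: int = 0

    def validate(self) -> None:
        rates = {
            "corruption_rate": self.corruption_rate,
            "distractor_rate": self.distractor_rate,
            "synonym_usage_rate": self.synonym_usage_rate,
            "coarse_age_rate": self.coarse_age_rate,
            "ambiguous_rate": self.ambiguous_rate,
            "table_fraction": self.table_fraction,
            "synonym_fraction": self.synonym_fraction,
            "species_fraction": self.species_fraction,
            "seed_kb_fraction": self.seed_kb_fraction,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for name in ("n_formations", "n_taxa", "n_documents"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mean_mentions < 1.0:
            raise ValueError("mean_mentions must be >= 1")
        if self.synonym_fraction > 0 and self.n_taxa < 2:
            raise ValueError("synonym pairs require at least 2 taxa")


@dataclass
class Document:
    doc_id: str
    pub_year: int
    sentences: list[list[str]] = field(default_factory=list)
    #: (row, col, tokens); (row, col) unique within the document
    table_cells: list[tuple[int, int, list[str]]] = field(default_factory=list)


@dataclass(frozen=True)
class MentionAnnotation:
    """A gold entity span: where an entity name was written in a document."""

    scope: str            # "sentence" or "table"
    index: int            # sentence index, or table row
    start: int            # token span, 0-based half-open (within the cell
    end: int              # for table scope)
    entity_type: str      # taxon | formation | interval | location
    entity_id: str
    col: int | None = None  # table column for table scope


@dataclass(frozen=True)
class SentenceFact:
    """What one sentence (or table row) asserts, and whether it is true.

    ``label=1`` marks a genuine fact rendering; ``label=0`` a distractor
    pairing that must not be extracted.  ``subject``/``object`` are the
    entity ids as *expressed* (a junior synonym stays junior here).
    """

    relation: str
    subject: str
    object: str
    label: int


@dataclass
class GoldWorld:
    config: WorldConfig
    gold_kb: list[KBTuple]
    documents: list[Document]
    #: doc_id -> list of gold mention spans
    annotations: dict[str, list[MentionAnnotation]]
    #: doc_id -> one entry per sentence (None = no relation asserted)
    sentence_facts: dict[str, list[SentenceFact | None]]
    #: doc_id -> table row -> fact
    table_facts: dict[str, dict[int, SentenceFact]]


# --------------------------------------------------------------------------
# vocabulary pools
# --------------------------------------------------------------------------

_SYLLABLES = [
    "bar", "bel", "cam", "cor", "dal", "dor", "el", "fen", "gal", "gor",
    "hal", "hol", "kar", "lan", "lum", "mar", "mon", "nor", "or", "pel",
    "quin", "ros", "sal", "sil", "tal", "tor", "ur", "vel", "wal", "yar",
]

_LITHOLOGY = ["Formation", "Shale", "Limestone", "Sandstone"]

_GENUS_SUFFIXES = [
    "ites", "ella", "oceras", "odus", "ina", "aspis", "onia", "ophyllum",
    "ichthys", "osaurus", "opora", "ospira",
]

_EPITHETS = [
    "minor", "elegans", "gracilis", "robustus", "tenuis", "ovata", "parva",
    "magna", "angulata", "simplex", "costata", "nodosa", "plana", "obscura",
    "rara", "typica", "media", "longa", "brevis", "crassa",
]

_LOCATIONS = [
    "Nevada", "Yunnan", "Estonia", "Queensland", "Bohemia", "Ohio", "Texas",
    "Morocco", "Siberia", "Gotland", "Wales", "Bavaria", "Sonora", "Alberta",
    "Xinjiang", "Oklahoma", "Iowa", "Kentucky", "Podolia", "Tasmania",
    "Patagonia", "Svalbard", "Oman", "Tibet", "Anhui", "Guizhou", "Colorado",
    "Montana", "Utah", "Wyoming", "Kansas", "Illinois", "Indiana",
    "Tennessee", "Alabama", "Arkansas", "Manitoba", "Yukon", "Ontario",
    "Scania",
]

# hedged ("weak") constructions differ in reliability: genuine facts favour
# the first templates, distractor pairings the later ones
_WEAK_TRUE_P = (0.5, 0.33, 0.17)
_WEAK_FALSE_P = (0.17, 0.33, 0.5)

_FILLERS = [
    "the section is well exposed along the river",
    "sampling was carried out at metre intervals",
    "the contact is sharp and planar",
    "preservation is generally excellent",
    "further collecting is planned for the area",
]

# Sentence templates per relation.  {S} and {O} are substituted by the
# subject and object surface tokens.  "strong" templates always express the
# relation; the single "weak" template is also used for false pairings, so
# its feature signature is genuinely ambiguous; "distractor" templates never
# express the relation.
_TEMPLATES: dict[str, dict[str, list[str]]] = {
    "formation_age": {
        "strong": [
            "the {S} is {O} in age",
            "the {S} was deposited during the {O}",
            "{O} strata of the {S} are richly fossiliferous",
            "fossils from the {S} indicate a {O} age",
            "the {S} dates to the {O}",
        ],
        "weak": [
            "{O} rocks crop out near the {S}",
            "the {S} may be {O} in age",
            "the {S} is possibly as old as the {O}",
        ],
        "distractor": [
            "the {S} is older than the {O}",
            "the {S} lacks {O} fossils",
        ],
    },
    "formation_location": {
        "strong": [
            "the {S} is exposed in {O}",
            "the {S} crops out across {O}",
            "outcrops of the {S} occur in {O}",
            "the {S} of {O} is described here",
            "sections of the {S} were measured in {O}",
        ],
        "weak": [
            "workers in {O} have examined the {S}",
            "the {S} may extend into {O}",
            "strata resembling the {S} occur in {O}",
        ],
        "distractor": ["the {S} does not extend into {O}"],
    },
    "taxon_in_formation": {
        "strong": [
            "{S} occurs in the {O}",
            "the {O} yields {S}",
            "specimens of {S} were collected from the {O}",
            "{S} is reported from the {O}",
            "the fauna of the {O} includes {S}",
        ],
        "weak": [
            "{S} was compared with material from the {O}",
            "{S} may occur in the {O}",
            "{S} is questionably recorded from the {O}",
        ],
        "distractor": [
            "{S} is absent from the {O}",
            "{S} has not been found in the {O}",
        ],
    },
    "opinion_belongs": {
        "strong": [
            "{S} belongs to the {O}",
            "{S} is assigned to the {O}",
            "{S} is a member of the {O}",
            "we refer {S} to the {O}",
            "{S} is placed in the {O}",
        ],
        "weak": [],
        "distractor": ["{S} is excluded from the {O}"],
    },
    "opinion_synonym": {
        "strong": [
            "{S} is a junior synonym of {O}",
            "{S} is here synonymized with {O}",
            "{S} is regarded as a synonym of {O}",
            "{S} is referred to {O} as a synonym",
            "the name {S} is a subjective synonym of {O}",
        ],
        "weak": [],
        "distractor": [
            "{S} is distinct from {O}",
            "{S} co-occurs with {O}",
        ],
    },
}


def _unique_names(rng: np.random.Generator, n: int, maker, taken: set[str]) -> list[str]:
    out: list[str] = []
    while len(out) < n:
        name = maker(rng)
        if name not in taken:
            taken.add(name)
            out.append(name)
    return out


def _formation_base(rng: np.random.Generator) -> str:
    k = int(rng.integers(2, 4))
    return "".join(rng.choice(_SYLLABLES) for _ in range(k)).capitalize()


def _genus_name(rng: np.random.Generator) -> str:
    stem = "".join(rng.choice(_SYLLABLES) for _ in range(int(rng.integers(1, 3))))
    return (stem + str(rng.choice(_GENUS_SUFFIXES))).capitalize()


def _family_name(rng: np.random.Generator) -> str:
    stem = "".join(rng.choice(_SYLLABLES) for _ in range(2))
    return stem.capitalize() + "idae"


def _location_name(rng: np.random.Generator) -> str:
    return "".join(rng.choice(_SYLLABLES) for _ in range(2)).capitalize() + " Basin"


# --------------------------------------------------------------------------
# world generation
# --------------------------------------------------------------------------

def generate_world(config: WorldConfig, table: IntervalTable) -> GoldWorld:
    """Build a deterministic gold world and its noisy document rendering."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    taken: set[str] = set()
    # --- entities --------------------------------------------------------
    formation_bases = _unique_names(rng, config.n_formations, _formation_base, taken)
    formations = [
        f"{base} {rng.choice(_LITHOLOGY)}" for base in formation_bases
    ]
    genera = _unique_names(rng, config.n_taxa, _genus_name, taken)
    n_families = max(3, config.n_taxa // 8) if config.n_taxa else 0
    families = _unique_names(rng, n_families, _family_name, taken)

    n_locations = min(len(_LOCATIONS), max(5, config.n_formations // 2))
    locations = list(rng.choice(_LOCATIONS, size=n_locations, replace=False))

    stages = sorted(iv.name for iv in table.intervals.values() if iv.rank == "stage")
    epochs = sorted(iv.name for iv in table.intervals.values() if iv.rank == "epoch")
    periods = sorted(iv.name for iv in table.intervals.values() if iv.rank == "period")

    # --- formation facts -------------------------------------------------
    formation_age: dict[str, str] = {}
    formation_loc: dict[str, str] = {}
    for f in formations:
        u = rng.random()
        if u < 0.70 and stages:
            age = str(rng.choice(stages))
        elif u < 0.90 and epochs:
            age = str(rng.choice(epochs))
        else:
            age = str(rng.choice(periods))
        formation_age[f] = age
        formation_loc[f] = str(rng.choice(locations)) if locations else ""

    def primary_bin(f: str) -> int | None:
        bins = table.bins_overlapping(formation_age[f])
        return bins[0] if bins else None

    # --- taxonomy --------------------------------------------------------
    genus_family = {g: str(rng.choice(families)) for g in genera} if families else {}
    n_juniors = int(round(config.synonym_fraction * len(genera)))
    juniors = _unique_names(rng, n_juniors, _genus_name, taken)
    senior_of: dict[str, str] = {}
    if juniors:
        seniors = rng.choice(genera, size=len(juniors), replace=False)
        senior_of = {j: str(s) for j, s in zip(juniors, seniors)}
    species_of: dict[str, str] = {}
    for g in genera:
        if rng.random() < config.species_fraction:
            species_of[g] = f"{g} {rng.choice(_EPITHETS)}"

    # --- occurrences ------------------------------------------------------
    # Each genus gets a home formation plus nearby-aged extras, so genus
    # stratigraphic ranges are contiguous-ish and the diversity curve has
    # structure.
    occurrences: set[tuple[str, str]] = set()
    if formations:
        f_bins = {f: primary_bin(f) for f in formations}
        for g in genera:
            home = str(rng.choice(formations))
            occurrences.add((g, home))
            hb = f_bins[home]
            if hb is not None:
                near = [
                    f for f in formations
                    if f != home and f_bins[f] is not None and abs(f_bins[f] - hb) <= 3
                ]
                k = min(len(near), int(rng.poisson(1.2)))
                if k:
                    for f in rng.choice(near, size=k, replace=False):
                        occurrences.add((g, str(f)))

    # --- gold KB ----------------------------------------------------------
    gold_kb: list[KBTuple] = []
    for f in formations:
        gold_kb.append(KBTuple("formation_age", f, formation_age[f]))
        if formation_loc[f]:
            gold_kb.append(KBTuple("formation_location", f, formation_loc[f]))
    for g, f in sorted(occurrences):
        gold_kb.append(KBTuple("taxon_in_formation", g, f))
    for g in genera:
        if genus_family:
            gold_kb.append(KBTuple("opinion_belongs", g, genus_family[g]))
    for g, sp in sorted(species_of.items()):
        gold_kb.append(KBTuple("opinion_belongs", sp, g))
    for j in juniors:
        gold_kb.append(KBTuple("opinion_synonym", j, senior_of[j]))

    # --- renderings -------------------------------------------------------
    junior_names_of = {}
    for j, s in senior_of.items():
        junior_names_of.setdefault(s, []).append(j)

    events: list[dict] = []  # sentence or table-row events
    for t in gold_kb:
        n_mentions = 1 + int(rng.poisson(config.mean_mentions - 1.0))
        for j in range(n_mentions):
            faithful = j == 0
            subj, obj = t.subject, t.object
            if not faithful:
                if (
                    t.relation == "taxon_in_formation"
                    and subj in junior_names_of
                    and rng.random() < config.synonym_usage_rate
                ):
                    subj = str(rng.choice(junior_names_of[subj]))
                if (
                    t.relation == "formation_age"
                    and rng.random() < config.coarse_age_rate
                ):
                    anc = table.ancestors(obj)
                    anc = [a for a in anc if table.get(a).rank in ("epoch", "period")]
                    if anc:
                        obj = str(rng.choice(anc))
            weak_ok = bool(_TEMPLATES[t.relation]["weak"]) and not faithful
            weak = weak_ok and rng.random() < config.ambiguous_rate
            weak_idx = int(rng.choice(3, p=_WEAK_TRUE_P)) if weak else 0
            as_table = (
                t.relation == "taxon_in_formation"
                and not weak
                and rng.random() < config.table_fraction
            )
            events.append(
                dict(
                    relation=t.relation, subject=subj, object=obj, label=1,
                    weak=weak, weak_idx=weak_idx, as_table=as_table,
                )
            )

    n_distract = int(round(config.distractor_rate * len(events)))
    for _ in range(n_distract):
        u = rng.random()
        if u < 0.4 and formations:
            # weak-template false pairing
            r = ["formation_age", "formation_location", "taxon_in_formation"][
                int(rng.integers(3))
            ]
            ev = _false_pair(
                rng, r, formations, genera, locations, stages + epochs,
                formation_age, formation_loc, occurrences, table,
            )
            if ev is not None:
                ev["weak"] = True
                ev["weak_idx"] = int(rng.choice(3, p=_WEAK_FALSE_P))
                events.append(ev)
        elif u < 0.8 and formations:
            r = str(rng.choice(list(_TEMPLATES)))
            ev = _false_pair(
                rng, r, formations, genera, locations, stages + epochs,
                formation_age, formation_loc, occurrences, table,
            )
            if ev is not None:
                ev["weak"] = False
                ev["distractor_template"] = True
                events.append(ev)
        else:
            events.append(dict(relation=None))

    # --- documents --------------------------------------------------------
    documents = [
        Document(doc_id=f"doc{k:04d}", pub_year=int(rng.integers(1950, 2016)))
        for k in range(config.n_documents)
    ]
    annotations: dict[str, list[MentionAnnotation]] = {d.doc_id: [] for d in documents}
    sentence_facts: dict[str, list[SentenceFact | None]] = {
        d.doc_id: [] for d in documents
    }
    table_facts: dict[str, dict[int, SentenceFact]] = {d.doc_id: {} for d in documents}

    order = rng.permutation(len(events))
    doc_of = rng.integers(0, max(config.n_documents, 1), size=len(events))
    for rank, ev_i in enumerate(order):
        ev = events[ev_i]
        if not documents:
            break
        doc = documents[int(doc_of[rank])]
        if ev.get("relation") is None:
            doc.sentences.append(str(rng.choice(_FILLERS)).split())
            sentence_facts[doc.doc_id].append(None)
            continue
        fact = SentenceFact(ev["relation"], ev["subject"], ev["object"], ev["label"])
        if ev.get("as_table"):
            _append_table_row(doc, fact, annotations[doc.doc_id], table_facts[doc.doc_id])
        else:
            _append_sentence(
                rng, doc, ev, fact, annotations[doc.doc_id], sentence_facts[doc.doc_id]
            )

    if config.corruption_rate > 0:
        documents = [
            corrupt_tokens(d, config.corruption_rate, rng) for d in documents
        ]

    return GoldWorld(
        config=config,
        gold_kb=gold_kb,
        documents=documents,
        annotations=annotations,
        sentence_facts=sentence_facts,
        table_facts=table_facts,
    )


def _false_pair(
    rng, relation, formations, genera, locations, intervals,
    formation_age, formation_loc, occurrences, table,
) -> dict | None:
    """A subject/object pairing that is genuinely false in the gold world."""
    for _ in range(20):
        if relation == "formation_age" and intervals:
            f = str(rng.choice(formations))
            iv = str(rng.choice(intervals))
            if not table.related(iv, formation_age[f]):
                return dict(relation=relation, subject=f, object=iv, label=0)
        elif relation == "formation_location" and locations:
            f = str(rng.choice(formations))
            loc = str(rng.choice(locations))
            if loc != formation_loc[f]:
                return dict(relation=relation, subject=f, object=loc, label=0)
        elif relation == "taxon_in_formation" and genera:
            g = str(rng.choice(genera))
            f = str(rng.choice(formations))
            if (g, f) not in occurrences:
                return dict(relation=relation, subject=g, object=f, label=0)
        elif relation == "opinion_belongs" and genera:
            a, b = rng.choice(genera, size=2, replace=False)
            return dict(relation=relation, subject=str(a), object=str(b), label=0)
        elif relation == "opinion_synonym" and len(genera) >= 2:
            a, b = rng.choice(genera, size=2, replace=False)
            return dict(relation=relation, subject=str(a), object=str(b), label=0)
        else:
            return None
    return None


def _surface_tokens(rng: np.random.Generator, entity_id: str, entity_type: str) -> list[str]:
    """How an entity is written; formations vary their lithology suffix."""
    if entity_type == "formation" and rng.random() < 0.25:
        base = entity_id.rsplit(" ", 1)[0]
        return [base, "Fm"] if rng.random() < 0.5 else [base, "Formation"]
    return entity_id.split()


_SUBJ_TYPE = {
    "formation_age": "formation",
    "formation_location": "formation",
    "taxon_in_formation": "taxon",
    "opinion_belongs": "taxon",
    "opinion_synonym": "taxon",
}
_OBJ_TYPE = {
    "formation_age": "interval",
    "formation_location": "location",
    "taxon_in_formation": "formation",
    "opinion_belongs": "taxon",
    "opinion_synonym": "taxon",
}


def _append_sentence(rng, doc, ev, fact, ann, facts) -> None:
    relation = ev["relation"]
    if ev.get("distractor_template"):
        template = str(rng.choice(_TEMPLATES[relation]["distractor"]))
        # distractor sentences assert nothing; keep them labelled 0 so the
        # candidate they spawn has a gold negative label
    elif ev.get("weak"):
        idx = min(ev.get("weak_idx", 0), len(_TEMPLATES[relation]["weak"]) - 1)
        template = _TEMPLATES[relation]["weak"][idx]
    else:
        template = str(rng.choice(_TEMPLATES[relation]["strong"]))
    subj_tokens = _surface_tokens(rng, ev["subject"], _SUBJ_TYPE[relation])
    obj_tokens = _surface_tokens(rng, ev["object"], _OBJ_TYPE[relation])
    tokens: list[str] = []
    spans: dict[str, tuple[int, int]] = {}
    for word in template.split():
        if word == "{S}":
            spans["S"] = (len(tokens), len(tokens) + len(subj_tokens))
            tokens.extend(subj_tokens)
        elif word == "{O}":
            spans["O"] = (len(tokens), len(tokens) + len(obj_tokens))
            tokens.extend(obj_tokens)
        else:
            tokens.append(word)
    sidx = len(doc.sentences)
    doc.sentences.append(tokens)
    facts.append(fact)
    ann.append(
        MentionAnnotation(
            "sentence", sidx, *spans["S"], _SUBJ_TYPE[relation], ev["subject"]
        )
    )
    ann.append(
        MentionAnnotation(
            "sentence", sidx, *spans["O"], _OBJ_TYPE[relation], ev["object"]
        )
    )


def _append_table_row(doc, fact, ann, tfacts) -> None:
    if not doc.table_cells:
        doc.table_cells.append((0, 0, ["Taxon"]))
        doc.table_cells.append((0, 1, ["Formation"]))
    row = max(r for r, _, _ in doc.table_cells) + 1
    subj_tokens = fact.subject.split()
    obj_tokens = fact.object.split()
    doc.table_cells.append((row, 0, subj_tokens))
    doc.table_cells.append((row, 1, obj_tokens))
    tfacts[row] = fact
    ann.append(
        MentionAnnotation("table", row, 0, len(subj_tokens), "taxon", fact.subject, 0)
    )
    ann.append(
        MentionAnnotation("table", row, 0, len(obj_tokens), "formation", fact.object, 1)
    )


# --------------------------------------------------------------------------
# noise, seed split, serialization
# --------------------------------------------------------------------------

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


def _mutate_token(token: str, rng: np.random.Generator) -> str:
    """Return a token guaranteed to differ from the input."""
    if len(token) > 1 and rng.random() < 0.5:
        i = int(rng.integers(len(token)))
        return token[:i] + token[i + 1:]
    i = int(rng.integers(len(token)))
    choices = [c for c in _ALPHABET if c != token[i]]
    return token[:i] + str(rng.choice(choices)) + token[i + 1:]


def corrupt_tokens(doc: Document, rate: float, rng: np.random.Generator) -> Document:
    """Independently corrupt each token with probability *rate*.

    Spans in any annotations remain valid: corruption changes characters,
    never token boundaries.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    new_sents = [
        [_mutate_token(t, rng) if rng.random() < rate else t for t in sent]
        for sent in doc.sentences
    ]
    new_cells = [
        (r, c, [_mutate_token(t, rng) if rng.random() < rate else t for t in toks])
        for r, c, toks in doc.table_cells
    ]
    return Document(doc.doc_id, doc.pub_year, new_sents, new_cells)


def split_seed_kb(
    gold_kb: Sequence[KBTuple], fraction: float, rng: np.random.Generator
) -> tuple[list[KBTuple], list[KBTuple]]:
    """Uniformly sample ``round(fraction * N)`` tuples as the seed KB."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    n = len(gold_kb)
    k = int(round(fraction * n))
    idx = set(rng.choice(n, size=k, replace=False).tolist()) if k else set()
    seed = [t for i, t in enumerate(gold_kb) if i in idx]
    holdout = [t for i, t in enumerate(gold_kb) if i not in idx]
    return seed, holdout


def write_corpus(world: GoldWorld, path: str | Path) -> None:
    """Serialize a world as line-delimited JSON records (one document/line)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps({"kind": "config", **asdict(world.config)}) + "\n")
        for t in world.gold_kb:
            fh.write(
                json.dumps(
                    {
                        "kind": "tuple",
                        "relation": t.relation,
                        "subject": t.subject,
                        "object": t.object,
                        "doc_id": t.doc_id,
                        "pub_year": t.pub_year,
                        "probability": t.probability,
                    }
                )
                + "\n"
            )
        for doc in world.documents:
            rec = {
                "kind": "document",
                "doc_id": doc.doc_id,
                "pub_year": doc.pub_year,
                "sentences": doc.sentences,
                "table_cells": [[r, c, toks] for r, c, toks in doc.table_cells],
                "annotations": [asdict(a) for a in world.annotations.get(doc.doc_id, [])],
                "sentence_facts": [
                    None if f is None else asdict(f)
                    for f in world.sentence_facts.get(doc.doc_id, [])
                ],
                "table_facts": {
                    str(row): asdict(f)
                    for row, f in world.table_facts.get(doc.doc_id, {}).items()
                },
            }
            fh.write(json.dumps(rec) + "\n")


def read_corpus(path: str | Path) -> GoldWorld:
    """Inverse of :func:`write_corpus`; raises on malformed lines."""
    config: WorldConfig | None = None
    gold_kb: list[KBTuple] = []
    documents: list[Document] = []
    annotations: dict[str, list[MentionAnnotation]] = {}
    sentence_facts: dict[str, list[SentenceFact | None]] = {}
    table_facts: dict[str, dict[int, SentenceFact]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                kind = rec.pop("kind")
            except (json.JSONDecodeError, KeyError) as exc:
                raise ValueError(f"{path}, line {lineno}: malformed record") from exc
            if kind == "config":
                config = WorldConfig(**rec)
            elif kind == "tuple":
                gold_kb.append(KBTuple(**rec))
            elif kind == "document":
                doc = Document(
                    doc_id=rec["doc_id"],
                    pub_year=rec["pub_year"],
                    sentences=[list(s) for s in rec["sentences"]],
                    table_cells=[(r, c, list(t)) for r, c, t in rec["table_cells"]],
                )
                documents.append(doc)
                annotations[doc.doc_id] = [
                    MentionAnnotation(**a) for a in rec["annotations"]
                ]
                sentence_facts[doc.doc_id] = [
                    None if f is None else SentenceFact(**f)
                    for f in rec["sentence_facts"]
                ]
                table_facts[doc.doc_id] = {
                    int(row): SentenceFact(**f)
                    for row, f in rec["table_facts"].items()
                }
            else:
                raise ValueError(f"{path}, line {lineno}: unknown record kind {kind!r}")
    if config is None:
        raise ValueError(f"{path}: missing config record")
    return GoldWorld(
        config=config,
        gold_kb=gold_kb,
        documents=documents,
        annotations=annotations,
        sentence_facts=sentence_facts,
        table_facts=table_facts,
    )
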