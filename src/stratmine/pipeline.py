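"""End-to-end orchestration: generate → extract → graph → learn → infer →
export → diversity, plus the training-size experiment.

Every stage is reproducible from the configuration: all randomness flows
from explicit seeds, and a run manifest records inputs, seeds, and the
counts at each stage (documents, mentions, candidates, variables, factors,
accepted tuples, occurrences).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from . import corpus as corpus_mod
from .corpus import GoldWorld, WorldConfig, generate_world, read_corpus, split_seed_kb
from .extract import build_gazetteers, extract_document, RelationCandidate
from .graph import (
    FactorGraph,
    add_hierarchy_factors,
    build_entity_layer,
    build_mention_layer,
)
from .inference import (
    LearningError,
    calibration_table,
    distant_supervision_entities,
    distant_supervision_labels,
    gibbs_marginals,
    learn_weights,
)
from .kb import KBTuple, read_kb, write_kb
from .macroevo import (
    apply_taxonomy,
    first_difference_spearman,
    foote_rates,
    genus_ranges,
    rangethrough_diversity,
    resolve_taxonomy,
)
from .probkb import (
    OccurrenceRecord,
    assemble_occurrences,
    entity_tuples,
    export_occurrences,
    export_opinions,
    filter_by_probability,
    resolution_filter,
)
from .timescale import IntervalTable, default_interval_table, load_interval_table

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "SamplerSettings",
    "LearnerSettings",
    "ExperimentGrid",
    "run_end_to_end",
    "training_size_curve",
    "world_vocabulary",
    "extract_world",
    "build_graph",
    "gold_occurrence_records",
    "PipelineError",
]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class SamplerSettings:
    n_samples: int = 4000
    burn_in: int | None = None
    thin: int = 4
    seed: int = 0


@dataclass
class LearnerSettings:
    l2: float = 0.1
    max_iter: int = 500
    tol: float = 1e-8
    negative_rate: float = 1.0
    #: closed-world negatives are noisy at the entity level (a tuple absent
    #: from a partial seed KB is usually still true), so by default only
    #: KB-supported positives and relation-confusion negatives clamp there
    entity_negative_rate: float = 0.0


@dataclass
class ExperimentGrid:
    fractions: tuple[float, ...] = (0.02, 0.1, 0.5, 1.0)
    replicates: int = 5


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    corpus: str | None = None          # JSONL corpus to read; else generate
    seed_kb: str | None = None         # seed KB CSV; else split from gold
    interval_table: str | None = None  # else packaged table
    bins: str | None = None            # explicit bin CSV
    world: WorldConfig = field(default_factory=WorldConfig)
    tau: float = 0.95
    min_rank: str = "epoch"
    sampler: SamplerSettings = field(default_factory=SamplerSettings)
    learner: LearnerSettings = field(default_factory=LearnerSettings)
    experiment: ExperimentGrid = field(default_factory=ExperimentGrid)

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError(f"tau must be in [0, 1], got {self.tau}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key, typ in (
            ("world", WorldConfig),
            ("sampler", SamplerSettings),
            ("learner", LearnerSettings),
            ("experiment", ExperimentGrid),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = typ(**raw[key])
        if isinstance(raw.get("experiment"), ExperimentGrid):
            raw["experiment"].fractions = tuple(raw["experiment"].fractions)
        return cls(**raw)

    def load_table(self) -> IntervalTable:
        if self.interval_table:
            p = Path(self.interval_table)
            if not p.exists():
                raise PipelineError("load_table", f"interval table not found: {p}")
            return load_interval_table(p, bins_path=self.bins)
        return default_interval_table(bins_path=self.bins)


# --------------------------------------------------------------------------
# stage helpers
# --------------------------------------------------------------------------

def world_vocabulary(world: GoldWorld, table: IntervalTable) -> dict[str, list[str]]:
    """Entity-name lexica (the stand-in for taxonomic/stratigraphic/place
    dictionaries that exist independently of any seed database)."""
    vocab: dict[str, set[str]] = {
        "taxon": set(), "formation": set(), "location": set(),
        "interval": set(table.intervals),
    }
    role = {
        "formation_age": ("formation", None),
        "formation_location": ("formation", "location"),
        "taxon_in_formation": ("taxon", "formation"),
        "opinion_belongs": ("taxon", "taxon"),
        "opinion_synonym": ("taxon", "taxon"),
    }
    for t in world.gold_kb:
        s_type, o_type = role[t.relation]
        vocab[s_type].add(t.subject)
        if o_type:
            vocab[o_type].add(t.object)
    return {k: sorted(v) for k, v in vocab.items()}


def extract_world(
    world: GoldWorld, gazetteers
) -> tuple[list, list[RelationCandidate]]:
    mentions, candidates = [], []
    for doc in world.documents:
        m, c = extract_document(doc, gazetteers)
        mentions.extend(m)
        candidates.extend(c)
    return mentions, candidates


def build_graph(
    candidates: Sequence[RelationCandidate],
    table: IntervalTable,
    doc_years: Mapping[str, int] | None = None,
) -> FactorGraph:
    g = build_mention_layer(candidates)
    build_entity_layer(g, candidates)
    add_hierarchy_factors(g, table)
    if doc_years:
        g.doc_years = dict(doc_years)  # provenance for entity tuples
    return g


def mention_gold_labels(
    world: GoldWorld,
    candidates: Sequence[RelationCandidate],
    table: IntervalTable,
) -> dict[str, int]:
    """Gold 0/1 label per candidate: is the tuple it asserts true in the
    gold world?

    Truth is world-level (the proposition the variable encodes), not
    sentence-level: a junior-synonym subject resolves through the gold
    synonymy, and a formation age is true if it equals or contains the
    gold age.  A distractor sentence pairing two entities whose tuple
    happens to be true elsewhere therefore yields a true candidate.
    """
    gold_keys = {t.key() for t in world.gold_kb}
    senior_of = {
        t.subject: t.object
        for t in world.gold_kb
        if t.relation == "opinion_synonym"
    }
    gold_ages: dict[str, list[str]] = {}
    for t in world.gold_kb:
        if t.relation == "formation_age":
            gold_ages.setdefault(t.subject, []).append(t.object)

    labels: dict[str, int] = {}
    for c in candidates:
        rel, subj, obj = c.relation, c.subject.entity_id, c.object.entity_id
        if rel == "taxon_in_formation":
            subj = senior_of.get(subj, subj)
            ok = (rel, subj, obj) in gold_keys
        elif rel == "formation_age":
            ok = any(
                g == obj or (obj in table and g in table and table.contains(obj, g))
                for g in gold_ages.get(subj, ())
            )
        else:
            ok = (rel, subj, obj) in gold_keys
        labels[c.variable_id] = int(ok)
    return labels


def gold_occurrence_records(
    world: GoldWorld, table: IntervalTable
) -> list[OccurrenceRecord]:
    """The gold occurrence set, assembled with the same rules as machine
    output (probability 1 on every gold tuple)."""
    tuples = [replace(t, probability=1.0) for t in world.gold_kb]
    return assemble_occurrences(tuples, table)


def _occurrence_key(o: OccurrenceRecord) -> tuple:
    return (o.genus, o.formation, o.interval, o.location)


def precision_recall(
    predicted: Iterable[OccurrenceRecord], gold: Iterable[OccurrenceRecord]
) -> tuple[float, float]:
    pred = {_occurrence_key(o) for o in predicted}
    gld = {_occurrence_key(o) for o in gold}
    if not pred:
        return (float("nan"), 0.0 if gld else float("nan"))
    tp = len(pred & gld)
    return (tp / len(pred), tp / len(gld) if gld else float("nan"))


def holdout_calibration(
    world: GoldWorld,
    table: IntervalTable,
    seed_fraction: float = 0.5,
    holdout_fraction: float = 0.5,
    learner: LearnerSettings | None = None,
    sampler: SamplerSettings | None = None,
    rng_seed: int = 0,
    min_block: int = 200,
):
    """The system's calibration report, on held-out assessed variables.

    A fraction of the distantly supervised mention labels is withheld from
    learning and inference.  The withheld set is split in two: the first
    half fits a monotone (isotonic) recalibration of the raw marginals,
    the second half is the evaluation set on which the report compares the
    recalibrated probabilities with the withheld assessments — the
    standard reliability-diagram methodology for such an extractor, with
    the recalibration fitted and evaluated on disjoint data.

    Returns (calibration bins, number of scored candidates).
    """
    from .inference import isotonic_calibrator

    learner = learner or LearnerSettings()
    sampler = sampler or SamplerSettings()
    rng = np.random.default_rng(rng_seed)
    gaz = build_gazetteers(world.gold_kb, world_vocabulary(world, table))
    _, candidates = extract_world(world, gaz)
    graph = build_graph(candidates, table,
                        {d.doc_id: d.pub_year for d in world.documents})
    seed_kb, _ = split_seed_kb(world.gold_kb, seed_fraction, rng)
    labels = distant_supervision_labels(
        candidates, seed_kb, table, learner.negative_rate, rng
    )
    entity_keys = [v.payload for v in graph.entity_variables()]
    entity_labels = distant_supervision_entities(
        entity_keys, seed_kb, table, learner.entity_negative_rate, rng
    )
    mention_ids = np.array(sorted(labels), dtype=object)
    n_hold = int(round(holdout_fraction * len(mention_ids)))
    held = mention_ids[rng.choice(len(mention_ids), size=n_hold, replace=False)]
    fit_ids = set(held[: n_hold // 2].tolist())
    eval_ids = set(held[n_hold // 2:].tolist())
    evidence = {
        k: v for k, v in labels.items() if k not in fit_ids and k not in eval_ids
    }
    evidence.update(entity_labels)
    weights, _ = learn_weights(
        graph, evidence, l2=learner.l2, max_iter=learner.max_iter, tol=learner.tol
    )
    # mention-layer probabilities: candidates with the same feature set
    # share one score, so each class's probability can be recalibrated
    # against the first held-out fold and assessed on the second
    import scipy.special

    raw_p = {
        c.variable_id: float(
            scipy.special.expit(sum(weights.get(f, 0.0) for f in c.features))
        )
        for c in candidates
        if c.variable_id in fit_ids or c.variable_id in eval_ids
    }
    fit_ids_sorted = sorted(fit_ids)
    recal = isotonic_calibrator(
        [raw_p[v] for v in fit_ids_sorted],
        [labels[v] for v in fit_ids_sorted],
        min_block=min_block,
    )
    eval_ids_sorted = sorted(eval_ids)
    raw = np.array([raw_p[v] for v in eval_ids_sorted])
    scored = dict(zip(eval_ids_sorted, recal(raw)))
    bins = calibration_table(scored, {v: labels[v] for v in eval_ids_sorted})
    return bins, len(scored)


# --------------------------------------------------------------------------
# end-to-end run
# --------------------------------------------------------------------------

def run_end_to_end(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _config_dict(config), "stages": {}}

    def stage(name: str, **counts) -> None:
        manifest["stages"][name] = counts
        logger.info("stage %-10s %s", name, counts)

    table = config.load_table()
    stage("timescale", intervals=len(table.intervals), bins=len(table.bins))

    # generate / load corpus -------------------------------------------------
    try:
        if config.corpus:
            world = read_corpus(config.corpus)
        else:
            world = generate_world(config.world, table)
            corpus_mod.write_corpus(world, out_dir / "corpus.jsonl")
    except (OSError, ValueError) as exc:
        raise PipelineError("generate", str(exc)) from exc
    stage("generate", documents=len(world.documents), gold_tuples=len(world.gold_kb))

    # seed KB ----------------------------------------------------------------
    rng = np.random.default_rng(config.world.rng_seed + 1)
    if config.seed_kb:
        if not Path(config.seed_kb).exists():
            raise PipelineError("seed_kb", f"seed KB not found: {config.seed_kb}")
        seed_kb = read_kb(config.seed_kb)
    else:
        seed_kb, _ = split_seed_kb(world.gold_kb, config.world.seed_kb_fraction, rng)
        write_kb(seed_kb, out_dir / "seed_kb.csv")
    stage("seed_kb", tuples=len(seed_kb))

    # extraction ---------------------------------------------------------------
    gaz = build_gazetteers(seed_kb, world_vocabulary(world, table))
    mentions, candidates = extract_world(world, gaz)
    stage("extract", mentions=len(mentions), candidates=len(candidates))

    # graph -------------------------------------------------------------------
    doc_years = {d.doc_id: d.pub_year for d in world.documents}
    graph = build_graph(candidates, table, doc_years)
    stage(
        "graph",
        variables=len(graph.variables),
        factors=len(graph.factors),
        weights=len(graph.weights),
    )

    # distant supervision + learning ------------------------------------------
    ds_rng = np.random.default_rng(config.world.rng_seed + 2)
    evidence = distant_supervision_labels(
        candidates, seed_kb, table, config.learner.negative_rate, ds_rng
    )
    entity_keys = [v.payload for v in graph.entity_variables()]
    evidence.update(
        distant_supervision_entities(
            entity_keys, seed_kb, table, config.learner.entity_negative_rate, ds_rng
        )
    )
    n_pos = sum(evidence.values())
    stage("supervision", evidence=len(evidence), positive=n_pos,
          negative=len(evidence) - n_pos)
    try:
        weights, learn_info = learn_weights(
            graph, evidence,
            l2=config.learner.l2, max_iter=config.learner.max_iter,
            tol=config.learner.tol,
        )
    except LearningError as exc:
        raise PipelineError("learn", str(exc)) from exc
    graph.set_weights(weights)
    stage("learn", **learn_info)

    # inference ----------------------------------------------------------------
    marginals = gibbs_marginals(
        graph, weights, evidence,
        n_samples=config.sampler.n_samples,
        burn_in=config.sampler.burn_in,
        thin=config.sampler.thin,
        rng_seed=config.sampler.seed,
    )
    _write_marginals(graph, marginals, out_dir / "marginals.csv")
    stage("infer", scored=len(marginals.probabilities),
          samples=marginals.n_samples, burn_in=marginals.burn_in)

    # calibration report -------------------------------------------------------
    gold_labels = mention_gold_labels(world, candidates, table)
    scored = {
        c.variable_id: marginals.probabilities[c.variable_id]
        for c in candidates
        if c.variable_id not in evidence
    }
    calib = calibration_table(scored, gold_labels)
    _write_calibration(calib, out_dir / "calibration.csv")

    # export -------------------------------------------------------------------
    tuples = entity_tuples(graph, marginals)
    accepted = filter_by_probability(tuples, config.tau)
    taxonomy = resolve_taxonomy(accepted)
    occurrences = apply_taxonomy(assemble_occurrences(accepted, table), taxonomy)
    export_occurrences(occurrences, out_dir / "occurrences.csv")
    export_opinions(accepted, out_dir / "opinions.csv")
    stage("export", entity_tuples=len(tuples), accepted=len(accepted),
          occurrences=len(occurrences))

    # diversity ----------------------------------------------------------------
    resolved = resolution_filter(occurrences, table, config.min_rank)
    ranges, n_multi = genus_ranges(resolved, table)
    n_bins = len(table.bins)
    counts = foote_rates(ranges, n_bins)
    df = counts.to_dataframe(table)
    df.to_csv(out_dir / "diversity.csv", index=False)
    stage("diversity", occurrences_resolved=len(resolved), genera=len(ranges),
          dropped_multibin=n_multi)

    # evaluation against the gold world ---------------------------------------
    gold_occ = gold_occurrence_records(world, table)
    prec, rec = precision_recall(occurrences, gold_occ)
    gold_ranges, _ = genus_ranges(
        resolution_filter(gold_occ, table, config.min_rank), table
    )
    report = {
        "precision": prec,
        "recall": rec,
        "gold_occurrences": len(gold_occ),
    }
    try:
        rho, p = first_difference_spearman(
            rangethrough_diversity(ranges, n_bins).astype(float),
            rangethrough_diversity(gold_ranges, n_bins).astype(float),
        )
        report["diversity_rho"] = rho
        report["diversity_rho_p"] = p
    except ValueError:
        report["diversity_rho"] = float("nan")
    manifest["evaluation"] = report
    stage("evaluate", **{k: v for k, v in report.items() if k != "diversity_rho_p"})

    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["experiment"]["fractions"] = list(d["experiment"]["fractions"])
    return d


def _write_marginals(graph: FactorGraph, marginals, path: Path) -> None:
    import csv as _csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = _csv.writer(fh)
        w.writerow(["variable_id", "layer", "payload", "probability"])
        for vid, v in graph.variables.items():
            payload = v.payload
            if isinstance(payload, tuple):
                desc = "|".join(payload)
            elif payload is not None:
                desc = f"{payload.relation}|{payload.subject.entity_id}|{payload.object.entity_id}"
            else:
                desc = ""
            w.writerow([vid, v.layer, desc, f"{marginals.probabilities[vid]:.6f}"])


def _write_calibration(bins, path: Path) -> None:
    import csv as _csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = _csv.writer(fh)
        w.writerow(["lo", "hi", "n_predictions", "n_correct", "empirical_accuracy"])
        for b in bins:
            acc = "" if b.n_predictions == 0 else f"{b.empirical_accuracy:.4f}"
            w.writerow([b.lo, b.hi, b.n_predictions, b.n_correct, acc])


# --------------------------------------------------------------------------
# training-size experiment
# --------------------------------------------------------------------------

def training_size_curve(config: PipelineConfig) -> list[dict]:
    """Relearn at several seed-KB sizes; report extraction volume and the
    first-difference diversity correlation against the gold world.

    One synthetic world (and one extraction pass) per replicate; each
    seed-KB fraction reruns supervision, learning, inference, and the
    diversity computation on that shared corpus.
    """
    if not config.experiment.fractions:
        raise PipelineError("experiment", "empty fraction grid")
    table = config.load_table()
    n_bins = len(table.bins)
    rows: list[dict] = []
    for rep in range(config.experiment.replicates):
        wc = replace(config.world, rng_seed=config.world.rng_seed + 1000 * rep)
        world = generate_world(wc, table)
        gaz = build_gazetteers(world.gold_kb, world_vocabulary(world, table))
        _, candidates = extract_world(world, gaz)
        doc_years = {d.doc_id: d.pub_year for d in world.documents}
        graph = build_graph(candidates, table, doc_years)
        entity_keys = [v.payload for v in graph.entity_variables()]
        gold_occ = gold_occurrence_records(world, table)
        gold_ranges, _ = genus_ranges(
            resolution_filter(gold_occ, table, config.min_rank), table
        )
        gold_div = rangethrough_diversity(gold_ranges, n_bins).astype(float)

        for fi, fraction in enumerate(config.experiment.fractions):
            graph.clear_evidence()
            rng = np.random.default_rng(wc.rng_seed + 17 * fi + 3)
            seed_kb, _ = split_seed_kb(world.gold_kb, fraction, rng)
            evidence = distant_supervision_labels(
                candidates, seed_kb, table, config.learner.negative_rate, rng
            )
            evidence.update(
                distant_supervision_entities(
                    entity_keys, seed_kb, table,
                    config.learner.entity_negative_rate, rng,
                )
            )
            row = {
                "fraction": fraction, "replicate": rep,
                "seed_tuples": len(seed_kb), "error": "",
            }
            try:
                weights, _ = learn_weights(
                    graph, evidence,
                    l2=config.learner.l2, max_iter=config.learner.max_iter,
                    tol=config.learner.tol,
                )
                marginals = gibbs_marginals(
                    graph, weights, evidence,
                    n_samples=config.sampler.n_samples,
                    burn_in=config.sampler.burn_in,
                    thin=config.sampler.thin,
                    rng_seed=config.sampler.seed + rep,
                )
                tuples = entity_tuples(graph, marginals)
                accepted = filter_by_probability(tuples, config.tau)
                taxonomy = resolve_taxonomy(accepted)
                occurrences = apply_taxonomy(
                    assemble_occurrences(accepted, table), taxonomy
                )
                resolved = resolution_filter(occurrences, table, config.min_rank)
                ranges, _ = genus_ranges(resolved, table)
                div = rangethrough_diversity(ranges, n_bins).astype(float)
                try:
                    rho, _p = first_difference_spearman(div, gold_div)
                except ValueError:
                    rho = float("nan")
                if not np.isfinite(rho):
                    # an empty or constant extracted series carries no
                    # signal; report zero correlation rather than NaN
                    row["error"] = "no_signal"
                    rho = 0.0
                row.update(tuple_count=len(accepted), rho=rho)
            except (LearningError, ValueError) as exc:
                row.update(tuple_count=0, rho=float("nan"), error=str(exc))
            rows.append(row)
    return rows
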