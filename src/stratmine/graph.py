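"""Boolean factor graph over mention- and entity-level relation variables.

The model is an exponential family over boolean variables: an assignment
``x`` has unnormalized log-probability ``sum_e phi_e(x_e)`` where each
factor (hyperedge) ``e`` contributes a weighted indicator potential.  Three
factor kinds realize the layered extraction model:

``unary_feature``
    One factor per (mention candidate, feature); ``phi = w * x_v``.
    Weights are tied by exact feature-string equality, so every expression
    of the same feature anywhere in the corpus shares one weight.
``aggregation``
    Links an entity-level variable to all mention-level variables asserting
    the same (relation, subject, object) tuple across documents;
    ``phi = w * 1{x_entity = max(x_mentions)}`` — an OR-like coupling that
    rewards the entity being true exactly when some mention is.
``implication``
    Between two entity variables (F, coarse interval) -> (F, fine interval)
    whenever the coarse interval contains the fine one; a statistical
    implication ``phi = w * 1{x_a = 0 or x_b = 1}`` whose strength is
    learned, not asserted.

Rule weights are tied globally under the ids ``RULE:aggregation`` and
``RULE:interval_implication``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .extract import RelationCandidate
from .timescale import IntervalTable

__all__ = [
    "Variable",
    "Factor",
    "FactorGraph",
    "CompiledGraph",
    "build_mention_layer",
    "build_entity_layer",
    "add_hierarchy_factors",
    "log_potential",
    "total_log_weight",
    "AGGREGATION_WEIGHT",
    "IMPLICATION_WEIGHT",
]

AGGREGATION_WEIGHT = "RULE:aggregation"
IMPLICATION_WEIGHT = "RULE:interval_implication"

KIND_UNARY = "unary_feature"
KIND_AGG = "aggregation"
KIND_IMPL = "implication"

_KIND_CODE = {KIND_UNARY: 0, KIND_AGG: 1, KIND_IMPL: 2}


@dataclass
class Variable:
    id: str
    layer: str                       # mention_relation | entity_relation
    is_evidence: bool = False
    evidence_value: int | None = None
    payload: object = None           # RelationCandidate or (rel, subj, obj)

    def set_evidence(self, value: int) -> None:
        self.is_evidence = True
        self.evidence_value = int(value)


@dataclass(frozen=True)
class Factor:
    id: int
    kind: str
    variable_ids: tuple[str, ...]
    weight_id: str

    def __post_init__(self) -> None:
        arity = len(self.variable_ids)
        if self.kind == KIND_UNARY and arity != 1:
            raise ValueError("unary_feature factors have arity 1")
        if self.kind == KIND_IMPL and arity != 2:
            raise ValueError("implication factors have arity 2")
        if self.kind == KIND_AGG and arity < 2:
            raise ValueError("aggregation factors link an entity to >=1 mentions")


class FactorGraph:
    """Variables, factors, and a tied weight vector."""

    def __init__(self) -> None:
        self.variables: dict[str, Variable] = {}
        self.factors: list[Factor] = []
        self.weights: dict[str, float] = {}

    # -- construction ----------------------------------------------------
    def add_variable(self, var: Variable) -> Variable:
        if var.id in self.variables:
            raise ValueError(f"duplicate variable id {var.id!r}")
        self.variables[var.id] = var
        return var

    def add_factor(self, kind: str, variable_ids: Sequence[str], weight_id: str) -> Factor:
        for vid in variable_ids:
            if vid not in self.variables:
                raise ValueError(f"factor references unknown variable {vid!r}")
        f = Factor(len(self.factors), kind, tuple(variable_ids), weight_id)
        self.factors.append(f)
        self.weights.setdefault(weight_id, 0.0)
        return f

    def set_weights(self, weights: Mapping[str, float]) -> None:
        for k, v in weights.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite weight for {k!r}")
            self.weights[k] = float(v)

    def clear_evidence(self) -> None:
        """Forget all evidence assignments (weights are kept)."""
        for v in self.variables.values():
            v.is_evidence = False
            v.evidence_value = None

    # -- views -----------------------------------------------------------
    def mention_variables(self) -> list[Variable]:
        return [v for v in self.variables.values() if v.layer == "mention_relation"]

    def entity_variables(self) -> list[Variable]:
        return [v for v in self.variables.values() if v.layer == "entity_relation"]

    def compile(self) -> "CompiledGraph":
        return CompiledGraph(self)

    # -- inspection dump --------------------------------------------------
    def dump_tsv(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        with open(f"{prefix}.variables.tsv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["id", "layer", "is_evidence", "evidence_value"])
            for v in self.variables.values():
                w.writerow([v.id, v.layer, int(v.is_evidence),
                            "" if v.evidence_value is None else v.evidence_value])
        with open(f"{prefix}.factors.tsv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["id", "kind", "weight_id", "variables"])
            for f in self.factors:
                w.writerow([f.id, f.kind, f.weight_id, "|".join(f.variable_ids)])
        with open(f"{prefix}.weights.tsv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["weight_id", "value"])
            for k in sorted(self.weights):
                w.writerow([k, self.weights[k]])


class CompiledGraph:
    """Array form of a :class:`FactorGraph` for the samplers and learner."""

    def __init__(self, graph: FactorGraph) -> None:
        self.graph = graph
        self.var_ids = list(graph.variables)
        self.var_index = {vid: i for i, vid in enumerate(self.var_ids)}
        n = len(self.var_ids)
        self.ev_mask = np.zeros(n, dtype=np.bool_)
        self.ev_val = np.zeros(n, dtype=np.int8)
        for vid, v in graph.variables.items():
            if v.is_evidence:
                i = self.var_index[vid]
                self.ev_mask[i] = True
                self.ev_val[i] = v.evidence_value

        self.weight_ids = sorted(graph.weights)
        self.weight_index = {w: i for i, w in enumerate(self.weight_ids)}
        self.w0 = np.array([graph.weights[w] for w in self.weight_ids], dtype=np.float64)

        nf = len(graph.factors)
        self.f_kind = np.zeros(nf, dtype=np.int8)
        self.f_widx = np.zeros(nf, dtype=np.int64)
        ptr = [0]
        fvars: list[int] = []
        for f in graph.factors:
            self.f_kind[f.id] = _KIND_CODE[f.kind]
            self.f_widx[f.id] = self.weight_index[f.weight_id]
            fvars.extend(self.var_index[v] for v in f.variable_ids)
            ptr.append(len(fvars))
        self.f_ptr = np.array(ptr, dtype=np.int64)
        self.f_vars = np.array(fvars, dtype=np.int64)

        # variable -> incident factors (CSR)
        counts = np.zeros(n, dtype=np.int64)
        for u in fvars:
            counts[u] += 1
        self.v_ptr = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(counts, out=self.v_ptr[1:])
        self.v_facs = np.zeros(len(fvars), dtype=np.int64)
        fill = self.v_ptr[:-1].copy()
        for f in graph.factors:
            for v in f.variable_ids:
                u = self.var_index[v]
                self.v_facs[fill[u]] = f.id
                fill[u] += 1

        self.free_vars = np.flatnonzero(~self.ev_mask).astype(np.int64)

    def weight_values(self, weights: Mapping[str, float] | None = None) -> np.ndarray:
        if weights is None:
            return self.w0.copy()
        return np.array(
            [weights.get(w, self.graph.weights.get(w, 0.0)) for w in self.weight_ids],
            dtype=np.float64,
        )


# --------------------------------------------------------------------------
# graph builders
# --------------------------------------------------------------------------

def build_mention_layer(candidates: Sequence[RelationCandidate]) -> FactorGraph:
    """One boolean variable per candidate; one tied unary factor per feature."""
    g = FactorGraph()
    for c in candidates:
        g.add_variable(Variable(id=c.variable_id, layer="mention_relation", payload=c))
        for feat in c.features:
            g.add_factor(KIND_UNARY, [c.variable_id], feat)
    return g


def entity_variable_id(relation: str, subject: str, object_: str) -> str:
    return f"e::{relation}::{subject}::{object_}"


def build_entity_layer(
    graph: FactorGraph, candidates: Sequence[RelationCandidate]
) -> FactorGraph:
    """Add one entity variable per distinct tuple plus aggregation factors.

    The entity variable is the cross-document assertion; its aggregation
    factor links it to every mention variable expressing the same tuple.
    """
    by_tuple: dict[tuple[str, str, str], list[str]] = {}
    for c in candidates:
        key = (c.relation, c.subject.entity_id, c.object.entity_id)
        by_tuple.setdefault(key, []).append(c.variable_id)
    for key in sorted(by_tuple):
        rel, subj, obj = key
        evid = entity_variable_id(rel, subj, obj)
        graph.add_variable(Variable(id=evid, layer="entity_relation", payload=key))
        graph.add_factor(KIND_AGG, [evid] + by_tuple[key], AGGREGATION_WEIGHT)
    return graph


def add_hierarchy_factors(graph: FactorGraph, table: IntervalTable) -> FactorGraph:
    """Implication factors between a formation's coarse and fine age tuples.

    For every formation with entity-level age candidates {a, b} where a
    strictly contains b, adds one (F, a) -> (F, b) implication with the
    shared learned weight.
    """
    ages: dict[str, list[str]] = {}
    for v in graph.entity_variables():
        rel, subj, obj = v.payload
        if rel == "formation_age":
            ages.setdefault(subj, []).append(obj)
    for formation in sorted(ages):
        ivs = sorted(set(ages[formation]))
        for a in ivs:
            for b in ivs:
                if a != b and a in table and b in table and table.contains(a, b):
                    graph.add_factor(
                        KIND_IMPL,
                        [
                            entity_variable_id("formation_age", formation, a),
                            entity_variable_id("formation_age", formation, b),
                        ],
                        IMPLICATION_WEIGHT,
                    )
    return graph


# --------------------------------------------------------------------------
# potentials
# --------------------------------------------------------------------------

def log_potential(
    factor: Factor, assignment: Mapping[str, int], weights: Mapping[str, float]
) -> float:
    """The weighted indicator potential of one factor under an assignment."""
    try:
        vals = [assignment[v] for v in factor.variable_ids]
    except KeyError as exc:
        raise KeyError(f"assignment missing variable {exc.args[0]!r}") from None
    w = weights[factor.weight_id]
    if factor.kind == KIND_UNARY:
        return w * vals[0]
    if factor.kind == KIND_IMPL:
        a, b = vals
        return w * (1.0 if (a == 0 or b == 1) else 0.0)
    if factor.kind == KIND_AGG:
        e, ms = vals[0], vals[1:]
        return w * (1.0 if e == max(ms) else 0.0)
    raise ValueError(f"unknown factor kind {factor.kind!r}")


def total_log_weight(
    graph: FactorGraph, assignment: Mapping[str, int],
    weights: Mapping[str, float] | None = None,
) -> float:
    """Unnormalized log-probability: the sum of all factor potentials."""
    w = weights if weights is not None else graph.weights
    return sum(log_potential(f, assignment, w) for f in graph.factors)
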