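"""Factor graph construction and potentials."""

import math

import pytest

from stratmine.corpus import Document
from stratmine.extract import build_gazetteers, extract_document
from stratmine.graph import (
    AGGREGATION_WEIGHT,
    FactorGraph,
    Factor,
    IMPLICATION_WEIGHT,
    Variable,
    add_hierarchy_factors,
    build_entity_layer,
    build_mention_layer,
    entity_variable_id,
    log_potential,
    total_log_weight,
)
from stratmine.kb import KBTuple


def _candidates(sentences, kb):
    gaz = build_gazetteers(kb, {})
    cands = []
    for i, s in enumerate(sentences):
        doc = Document(f"d{i}", 1990 + i, sentences=[s.split()])
        _, cs = extract_document(doc, gaz)
        cands.extend(cs)
    return cands


KB = [
    KBTuple("formation_age", "Tsingyuan Fm", "Namurian"),
    KBTuple("formation_age", "Tsingyuan Fm", "Carboniferous"),
    KBTuple("formation_age", "Tsingyuan Fm", "Devonian"),
]


class TestMentionLayer:
    def test_one_variable_per_candidate_one_factor_per_feature(self):
        cands = _candidates(["the Tsingyuan Fm is Namurian in age"], KB)
        assert len(cands) == 1
        g = build_mention_layer(cands)
        assert len(g.variables) == 1
        assert len(g.factors) == len(cands[0].features)
        assert all(f.kind == "unary_feature" for f in g.factors)

    def test_empty_candidates_empty_graph(self):
        g = build_mention_layer([])
        assert not g.variables and not g.factors

    def test_shared_feature_ties_one_weight(self):
        cands = _candidates(
            ["the Tsingyuan Fm is Namurian in age",
             "the Tsingyuan Fm is Carboniferous in age"],
            KB,
        )
        g = build_mention_layer(cands)
        assert len(g.variables) == 2
        # two factors per shared feature string but a single weight entry
        feature_factors = [f for f in g.factors if f.weight_id == "formation_age::BTW=is"]
        assert len(feature_factors) == 2
        assert sum(1 for w in g.weights if w == "formation_age::BTW=is") == 1

    def test_duplicate_variable_id_rejected(self):
        g = FactorGraph()
        g.add_variable(Variable("x", "mention_relation"))
        with pytest.raises(ValueError, match="duplicate"):
            g.add_variable(Variable("x", "mention_relation"))


class TestEntityLayer:
    def test_three_mentions_one_entity_arity_four(self):
        cands = _candidates(
            ["the Tsingyuan Fm is Namurian in age"] * 3, KB
        )
        g = build_mention_layer(cands)
        build_entity_layer(g, cands)
        evs = g.entity_variables()
        assert len(evs) == 1
        assert evs[0].payload == ("formation_age", "Tsingyuan Fm", "Namurian")
        agg = [f for f in g.factors if f.kind == "aggregation"]
        assert len(agg) == 1
        assert len(agg[0].variable_ids) == 4

    def test_no_candidates_no_entities(self):
        g = build_mention_layer([])
        build_entity_layer(g, [])
        assert g.entity_variables() == []


class TestHierarchyFactors:
    def _graph(self, sentences):
        cands = _candidates(sentences, KB)
        g = build_mention_layer(cands)
        build_entity_layer(g, cands)
        return g

    def test_containing_pair_gets_one_implication(self, table):
        g = self._graph(
            ["the Tsingyuan Fm is Namurian in age",
             "the Tsingyuan Fm is Carboniferous in age"]
        )
        add_hierarchy_factors(g, table)
        impl = [f for f in g.factors if f.kind == "implication"]
        assert len(impl) == 1
        assert impl[0].variable_ids == (
            entity_variable_id("formation_age", "Tsingyuan Fm", "Carboniferous"),
            entity_variable_id("formation_age", "Tsingyuan Fm", "Namurian"),
        )
        assert impl[0].weight_id == IMPLICATION_WEIGHT

    def test_single_age_no_implication(self, table):
        g = self._graph(["the Tsingyuan Fm is Namurian in age"])
        add_hierarchy_factors(g, table)
        assert [f for f in g.factors if f.kind == "implication"] == []

    def test_disjoint_ages_no_implication(self, table):
        g = self._graph(
            ["the Tsingyuan Fm is Namurian in age",
             "the Tsingyuan Fm is Devonian in age"]
        )
        add_hierarchy_factors(g, table)
        assert [f for f in g.factors if f.kind == "implication"] == []


class TestPotentials:
    def _factor(self, kind, var_ids, wid="w"):
        return Factor(0, kind, tuple(var_ids), wid)

    @pytest.mark.parametrize(
        "kind,var_ids,assignment,weight,expected",
        [
            ("unary_feature", ["a"], {"a": 1}, 2.0, 2.0),
            ("unary_feature", ["a"], {"a": 0}, 2.0, 0.0),
            ("implication", ["a", "b"], {"a": 1, "b": 0}, 1.5, 0.0),
            ("implication", ["a", "b"], {"a": 0, "b": 0}, 1.5, 1.5),
            ("implication", ["a", "b"], {"a": 1, "b": 1}, 1.5, 1.5),
            ("aggregation", ["e", "m1", "m2"], {"e": 1, "m1": 0, "m2": 1}, 1.0, 1.0),
            ("aggregation", ["e", "m1", "m2"], {"e": 1, "m1": 0, "m2": 0}, 1.0, 0.0),
            ("aggregation", ["e", "m1", "m2"], {"e": 0, "m1": 0, "m2": 0}, 1.0, 1.0),
        ],
    )
    def test_log_potential_cases(self, kind, var_ids, assignment, weight, expected):
        f = self._factor(kind, var_ids)
        assert log_potential(f, assignment, {"w": weight}) == expected

    def test_missing_variable_raises(self):
        f = self._factor("implication", ["a", "b"])
        with pytest.raises(KeyError, match="b"):
            log_potential(f, {"a": 1}, {"w": 1.0})

    def test_total_log_weight_is_sum_of_potentials(self, table):
        cands = _candidates(
            ["the Tsingyuan Fm is Namurian in age",
             "the Tsingyuan Fm is Carboniferous in age"],
            KB,
        )
        g = build_mention_layer(cands)
        build_entity_layer(g, cands)
        add_hierarchy_factors(g, table)
        g.set_weights({w: 0.5 for w in g.weights})
        assignment = {vid: 1 for vid in g.variables}
        expected = sum(log_potential(f, assignment, g.weights) for f in g.factors)
        assert total_log_weight(g, assignment) == pytest.approx(expected)

    def test_construction_is_deterministic(self, table):
        sentences = [
            "the Tsingyuan Fm is Namurian in age",
            "the Tsingyuan Fm is Carboniferous in age",
        ]
        graphs = []
        for _ in range(2):
            cands = _candidates(sentences, KB)
            g = build_mention_layer(cands)
            build_entity_layer(g, cands)
            add_hierarchy_factors(g, table)
            graphs.append(g)
        assert list(graphs[0].variables) == list(graphs[1].variables)
        assert [
            (f.kind, f.variable_ids, f.weight_id) for f in graphs[0].factors
        ] == [(f.kind, f.variable_ids, f.weight_id) for f in graphs[1].factors]

    def test_arity_constraints(self):
        with pytest.raises(ValueError):
            Factor(0, "unary_feature", ("a", "b"), "w")
        with pytest.raises(ValueError):
            Factor(0, "implication", ("a",), "w")
        with pytest.raises(ValueError):
            Factor(0, "aggregation", ("e",), "w")
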