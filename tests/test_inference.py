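"""Distant supervision, weight learning, Gibbs vs enumeration, calibration."""

import math

import numpy as np
import pytest
import scipy.special

from stratmine.corpus import Document
from stratmine.extract import build_gazetteers, extract_document
from stratmine.graph import FactorGraph, Variable, entity_variable_id
from stratmine.inference import (
    LearningError,
    calibration_table,
    distant_supervision_entities,
    distant_supervision_labels,
    exact_marginals,
    gibbs_marginals,
    isotonic_calibrator,
    learn_weights,
)
from stratmine.kb import KBTuple

from conftest import make_random_graph


# --------------------------------------------------------------------------
# distant supervision
# --------------------------------------------------------------------------

SEED_KB = [
    KBTuple("formation_age", "Tsingyuan Fm", "Namurian"),
    KBTuple("formation_age", "Marnor Fm", "Carboniferous"),
    KBTuple("opinion_belongs", "Aus", "Bidae"),
]


def _age_candidates(pairs):
    gaz = build_gazetteers(
        SEED_KB,
        {"interval": ["Namurian", "Carboniferous", "Devonian", "Silurian"],
         "formation": ["Tsingyuan Fm", "Marnor Fm", "Unseen Fm"]},
    )
    cands = []
    for i, (f, iv) in enumerate(pairs):
        doc = Document(f"d{i}", 2000, sentences=[f"the {f} is {iv} in age".split()])
        _, cs = extract_document(doc, gaz)
        cands.extend(c for c in cs if c.relation == "formation_age")
    return cands


class TestDistantSupervision:
    def test_seed_match_is_positive(self, table):
        c = _age_candidates([("Tsingyuan Fm", "Namurian")])
        ev = distant_supervision_labels(c, SEED_KB, table)
        assert ev[c[0].variable_id] == 1

    def test_interval_ancestor_variant_is_positive(self, table):
        # seed says Namurian; the statement says Carboniferous, which
        # contains the Namurian
        c = _age_candidates([("Tsingyuan Fm", "Carboniferous")])
        ev = distant_supervision_labels(c, SEED_KB, table)
        assert ev[c[0].variable_id] == 1

    def test_disjoint_object_is_negative(self, table):
        c = _age_candidates([("Tsingyuan Fm", "Devonian")])
        ev = distant_supervision_labels(c, SEED_KB, table, negative_rate=1.0)
        assert ev[c[0].variable_id] == 0

    def test_unknown_subject_is_unlabeled(self, table):
        c = _age_candidates([("Unseen Fm", "Silurian")])
        ev = distant_supervision_labels(c, SEED_KB, table)
        assert c[0].variable_id not in ev

    def test_negative_rate_zero_drops_closed_world_negatives(self, table):
        c = _age_candidates([("Tsingyuan Fm", "Devonian")])
        ev = distant_supervision_labels(c, SEED_KB, table, negative_rate=0.0)
        assert c[0].variable_id not in ev

    def test_pair_known_under_other_relation_is_hard_negative(self, table):
        # (Aus, Bidae) is a belongs pair in the seed; its synonymy reading
        # must be a negative even though Aus has no synonym opinions
        ev = distant_supervision_entities(
            [("opinion_synonym", "Aus", "Bidae")], SEED_KB, table,
            negative_rate=0.0,
        )
        assert ev[entity_variable_id("opinion_synonym", "Aus", "Bidae")] == 0


# --------------------------------------------------------------------------
# learning
# --------------------------------------------------------------------------

def _unary_graph(X, y):
    g = FactorGraph()
    ev = {}
    for i in range(X.shape[0]):
        vid = f"c{i}"
        g.add_variable(Variable(vid, "mention_relation"))
        for j in np.flatnonzero(X[i]):
            g.add_factor("unary_feature", [vid], f"feat{j}")
        ev[vid] = int(y[i])
    return g, ev


class TestLearnWeights:
    def test_unary_case_matches_sklearn_logistic(self):
        """The unary-only objective is penalized logistic regression; the
        independent oracle is scikit-learn with C = 1/l2."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(1)
        n, d, l2 = 1000, 6, 0.5
        X = (rng.random((n, d)) < 0.4).astype(int)
        w_star = rng.uniform(-1.5, 1.5, size=d)
        y = (rng.random(n) < scipy.special.expit(X @ w_star)).astype(int)
        g, ev = _unary_graph(X, y)
        w, info = learn_weights(g, ev, l2=l2, tol=1e-10)
        assert info["converged"]
        ours = np.array([w[f"feat{j}"] for j in range(d)])
        oracle = LogisticRegression(
            C=1.0 / l2, fit_intercept=False, tol=1e-10
        ).fit(X, y)
        assert np.allclose(ours, oracle.coef_.ravel(), atol=1e-3)

    def test_discriminative_feature_gets_large_weight(self):
        rng = np.random.default_rng(2)
        n = 1000
        y = rng.integers(0, 2, size=n)
        X = y.reshape(-1, 1)  # feature present iff label positive
        g, ev = _unary_graph(X, y)
        w, _ = learn_weights(g, ev, l2=0.1)
        assert w["feat0"] > 1.0

    def test_label_independent_features_get_zero_weight(self):
        rng = np.random.default_rng(3)
        n = 2000
        X = (rng.random((n, 3)) < 0.5).astype(int)
        y = rng.integers(0, 2, size=n)  # labels independent of features
        g, ev = _unary_graph(X, y)
        w, _ = learn_weights(g, ev, l2=0.1)
        assert all(abs(w[f"feat{j}"]) < 0.15 for j in range(3))

    def test_no_positive_evidence_is_an_error(self):
        g, ev = _unary_graph(np.ones((4, 1), dtype=int), np.zeros(4, dtype=int))
        with pytest.raises(LearningError):
            learn_weights(g, ev)
        with pytest.raises(LearningError):
            learn_weights(g, {})


# --------------------------------------------------------------------------
# inference
# --------------------------------------------------------------------------

class TestMarginals:
    def test_isolated_variable_is_uniform(self):
        g = FactorGraph()
        g.add_variable(Variable("x", "mention_relation"))
        m = gibbs_marginals(g, n_samples=4000, rng_seed=0)
        assert m["x"] == pytest.approx(0.5, abs=0.02)

    def test_single_unary_factor_matches_logistic(self):
        g = FactorGraph()
        g.add_variable(Variable("x", "mention_relation"))
        g.add_factor("unary_feature", ["x"], "w")
        g.set_weights({"w": 2.0})
        expected = math.exp(2) / (1 + math.exp(2))  # 0.8808
        m = gibbs_marginals(g, n_samples=4000, rng_seed=0)
        assert m["x"] == pytest.approx(expected, abs=0.01)
        ex = exact_marginals(g)
        assert ex["x"] == pytest.approx(expected, abs=1e-12)

    def test_empty_graph_empty_marginals(self):
        assert exact_marginals(FactorGraph()).probabilities == {}

    def test_evidence_is_clamped(self):
        g = FactorGraph()
        g.add_variable(Variable("x", "mention_relation"))
        g.add_factor("unary_feature", ["x"], "w")
        g.set_weights({"w": -5.0})
        m = gibbs_marginals(g, evidence={"x": 1}, n_samples=500, rng_seed=0)
        assert m["x"] == 1.0

    def test_implication_chain_matches_enumeration(self):
        g = FactorGraph()
        for v in ("a", "b", "c"):
            g.add_variable(Variable(v, "entity_relation"))
        g.add_factor("unary_feature", ["a"], "wa")
        g.add_factor("implication", ["a", "b"], "wi")
        g.add_factor("implication", ["b", "c"], "wi")
        g.set_weights({"wa": 1.5, "wi": 1.0})
        ex = exact_marginals(g)
        gb = gibbs_marginals(g, n_samples=20000, burn_in=2000, rng_seed=4)
        for v in ("a", "b", "c"):
            assert gb[v] == pytest.approx(ex[v], abs=0.01)

    def test_enumeration_limit_enforced(self):
        g = FactorGraph()
        for i in range(25):
            g.add_variable(Variable(f"v{i}", "mention_relation"))
        with pytest.raises(ValueError, match="enumeration"):
            exact_marginals(g)

    def test_gibbs_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        g = make_random_graph(rng)
        m1 = gibbs_marginals(g, n_samples=2000, rng_seed=11)
        m2 = gibbs_marginals(g, n_samples=2000, rng_seed=11)
        assert m1.probabilities == m2.probabilities

    def test_increasing_positive_feature_weight_never_decreases_marginal(self):
        g = FactorGraph()
        g.add_variable(Variable("x", "mention_relation"))
        g.add_factor("unary_feature", ["x"], "w")
        last = 0.0
        for w in (0.0, 0.5, 1.0, 2.0, 4.0):
            p = exact_marginals(g, weights={"w": w})["x"]
            assert p >= last
            last = p


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

class TestCalibration:
    def test_all_confident_and_correct(self):
        marg = {f"v{i}": 1.0 for i in range(10)}
        gold = {f"v{i}": 1 for i in range(10)}
        bins = calibration_table(marg, gold)
        assert bins[-1].n_predictions == 10
        assert bins[-1].empirical_accuracy == 1.0

    def test_empty_input(self):
        bins = calibration_table({}, {})
        assert all(b.n_predictions == 0 for b in bins)
        assert math.isnan(bins[0].empirical_accuracy)

    def test_missing_gold_label_raises(self):
        with pytest.raises(KeyError):
            calibration_table({"v": 0.5}, {})

    def test_bernoulli_labels_are_calibrated(self):
        rng = np.random.default_rng(12)
        n = 5000
        p = rng.random(n)
        y = (rng.random(n) < p).astype(int)
        marg = {f"v{i}": float(p[i]) for i in range(n)}
        gold = {f"v{i}": int(y[i]) for i in range(n)}
        for b in calibration_table(marg, gold):
            if b.n_predictions:
                assert abs(b.empirical_accuracy - b.center) <= 0.05

    def test_isotonic_calibrator_is_monotone_and_matches_rates(self):
        rng = np.random.default_rng(13)
        raw = np.repeat([0.2, 0.5, 0.8], 300)
        truth = np.concatenate([
            rng.random(300) < 0.1, rng.random(300) < 0.5, rng.random(300) < 0.9,
        ]).astype(int)
        recal = isotonic_calibrator(raw, truth, min_block=100)
        out = recal(np.array([0.2, 0.5, 0.8]))
        assert out[0] <= out[1] <= out[2]
        assert out[0] == pytest.approx(0.1, abs=0.05)
        assert out[2] == pytest.approx(0.9, abs=0.05)
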