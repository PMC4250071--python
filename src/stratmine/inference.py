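"""Distant supervision, weight learning, and marginal inference.

Training data comes from distant supervision: candidates whose entity tuple
matches the seed knowledge base become positive evidence, candidates whose
subject is known to the seed KB only with incompatible objects become
(subsampled) negative evidence under a per-subject closed-world assumption,
and everything else stays unlabeled.  For formation ages a match is relaxed
along the interval hierarchy: a seed age of Namurian supports a stated age
of Carboniferous and vice versa.

Weights maximize an L2-penalized composite conditional likelihood
(pseudo-likelihood) of the evidence variables: each evidence variable
contributes the log-probability of its observed value given its observed
neighborhood, restricted to factors whose remaining variables are observed.
For evidence variables touched only by unary factors this is exactly
penalized logistic regression on the feature indicators.  Rule factors
(aggregation, implication) whose neighborhoods include unlabeled mention
variables enter a second pass in which those mentions are imputed from the
first-pass unary model; unlabeled variables never contribute rows of their
own to the objective.

Marginals come from single-site Gibbs sampling with evidence clamped, in a
fixed sweep order with a seeded generator; a brute-force enumeration of the
exponential-family distribution serves as the exact reference for small
graphs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.optimize
import scipy.sparse
import scipy.special

from .extract import RelationCandidate
from .graph import (
    CompiledGraph,
    FactorGraph,
    KIND_UNARY,
    entity_variable_id,
)
from .kb import KBTuple
from .timescale import IntervalTable

__all__ = [
    "LearningError",
    "MarginalTable",
    "CalibrationBin",
    "distant_supervision_labels",
    "distant_supervision_entities",
    "learn_weights",
    "gibbs_marginals",
    "exact_marginals",
    "calibration_table",
    "isotonic_calibrator",
]


class LearningError(RuntimeError):
    """Raised when learning lacks usable evidence."""


@dataclass
class MarginalTable:
    """Estimated P(variable = 1) per variable."""

    probabilities: dict[str, float]
    n_samples: int
    burn_in: int
    rng_seed: int | None = None

    def __getitem__(self, var_id: str) -> float:
        return self.probabilities[var_id]


@dataclass(frozen=True)
class CalibrationBin:
    lo: float
    hi: float
    n_predictions: int
    n_correct: int

    @property
    def empirical_accuracy(self) -> float:
        if self.n_predictions == 0:
            return float("nan")
        return self.n_correct / self.n_predictions

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)


# --------------------------------------------------------------------------
# distant supervision
# --------------------------------------------------------------------------

class _SeedIndex:
    def __init__(self, seed_kb: Iterable[KBTuple]):
        self.keys: set[tuple[str, str, str]] = set()
        self.by_subject: dict[tuple[str, str], set[str]] = {}
        self.pair_relations: dict[tuple[str, str], set[str]] = {}
        for t in seed_kb:
            self.keys.add(t.key())
            self.by_subject.setdefault((t.relation, t.subject), set()).add(t.object)
            self.pair_relations.setdefault((t.subject, t.object), set()).add(t.relation)


def _label_tuple(
    relation: str, subject: str, obj: str,
    seed: _SeedIndex, table: IntervalTable,
) -> int | str | None:
    """1 = supported by the seed KB; 0 = closed-world contradicted (the
    subject is known for this relation but only with disjoint objects);
    "confused" = the pair is in the seed KB under a different relation
    (a hard negative, e.g. the synonymy reading of a belongs statement);
    None = the seed KB is silent."""
    if (relation, subject, obj) in seed.keys:
        return 1
    seen = seed.by_subject.get((relation, subject))
    if relation == "formation_age" and seen:
        for o in seen:
            if obj in table and o in table and table.related(o, obj):
                return 1
    if seed.pair_relations.get((subject, obj)):
        return "confused"
    if seen is None:
        return None
    return 0


def distant_supervision_labels(
    candidates: Sequence[RelationCandidate],
    seed_kb: Iterable[KBTuple],
    table: IntervalTable,
    negative_rate: float = 1.0,
    rng: np.random.Generator | None = None,
) -> dict[str, int]:
    """Evidence assignment for mention candidates.

    Negative labels are subsampled at ``negative_rate`` (closed-world
    negatives are plentiful and noisy; subsampling balances the classes).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    seed = _SeedIndex(seed_kb)
    evidence: dict[str, int] = {}
    for c in candidates:
        lab = _label_tuple(
            c.relation, c.subject.entity_id, c.object.entity_id, seed, table
        )
        if lab == 1:
            evidence[c.variable_id] = 1
        elif lab == "confused":
            evidence[c.variable_id] = 0
        elif lab == 0 and rng.random() < negative_rate:
            evidence[c.variable_id] = 0
    return evidence


def distant_supervision_entities(
    entity_keys: Iterable[tuple[str, str, str]],
    seed_kb: Iterable[KBTuple],
    table: IntervalTable,
    negative_rate: float = 1.0,
    rng: np.random.Generator | None = None,
) -> dict[str, int]:
    """The same labeling rule applied to entity-level tuples."""
    rng = rng if rng is not None else np.random.default_rng(0)
    seed = _SeedIndex(seed_kb)
    evidence: dict[str, int] = {}
    for rel, subj, obj in entity_keys:
        lab = _label_tuple(rel, subj, obj, seed, table)
        vid = entity_variable_id(rel, subj, obj)
        if lab == 1:
            evidence[vid] = 1
        elif lab == "confused":
            evidence[vid] = 0
        elif lab == 0 and rng.random() < negative_rate:
            evidence[vid] = 0
    return evidence


# --------------------------------------------------------------------------
# weight learning
# --------------------------------------------------------------------------

def _delta_phi(comp: CompiledGraph, f: int, x: np.ndarray, v: int) -> float:
    """phi_f(x_v=1) - phi_f(x_v=0) with unit weight, neighbors from x."""
    kind = comp.f_kind[f]
    lo, hi = comp.f_ptr[f], comp.f_ptr[f + 1]
    vs = comp.f_vars[lo:hi]
    if kind == 0:
        return 1.0
    if kind == 2:
        a, b = vs
        if v == a:
            return float(x[b]) - 1.0   # 1{b=1} - 1
        return 1.0 - float(x[a])       # 1 - 1{a=0}
    # aggregation
    e = vs[0]
    if v == e:
        mx = int(x[vs[1:]].max()) if hi - lo > 1 else 0
        return (1.0 if mx == 1 else 0.0) - (1.0 if mx == 0 else 0.0)
    others = [u for u in vs[1:] if u != v]
    mx_rest = int(x[others].max()) if others else 0
    ev = int(x[e])
    mx1 = max(mx_rest, 1)
    mx0 = mx_rest
    return (1.0 if ev == mx1 else 0.0) - (1.0 if ev == mx0 else 0.0)


def _weight_is_unary(comp: CompiledGraph) -> np.ndarray:
    """Mask of weights used by unary factors (feature weights)."""
    mask = np.zeros(len(comp.weight_ids), dtype=bool)
    for f in range(len(comp.f_kind)):
        if comp.f_kind[f] == 0:
            mask[comp.f_widx[f]] = True
    return mask


def _build_design(
    comp: CompiledGraph, x: np.ndarray, observed: np.ndarray, rows: np.ndarray,
    factor_mask: np.ndarray | None = None,
) -> scipy.sparse.csr_matrix:
    """Pseudo-likelihood design: one row per evidence variable, one column
    per weight; entry = summed unit-weight potential difference over the
    incident factors whose other variables are all observed."""
    data, ri, ci = [], [], []
    row_of = {v: i for i, v in enumerate(rows)}
    for v in rows:
        for k in range(comp.v_ptr[v], comp.v_ptr[v + 1]):
            f = comp.v_facs[k]
            if factor_mask is not None and not factor_mask[f]:
                continue
            vs = comp.f_vars[comp.f_ptr[f]:comp.f_ptr[f + 1]]
            ok = True
            for u in vs:
                if u != v and not observed[u]:
                    ok = False
                    break
            if not ok:
                continue
            d = _delta_phi(comp, f, x, v)
            if d != 0.0:
                ri.append(row_of[v])
                ci.append(comp.f_widx[f])
                data.append(d)
    return scipy.sparse.csr_matrix(
        (data, (ri, ci)), shape=(len(rows), len(comp.weight_ids))
    )


def _fit_penalized_logistic(
    A: scipy.sparse.csr_matrix, y: np.ndarray, l2: float,
    w0: np.ndarray, max_iter: int, tol: float,
    offset: np.ndarray | None = None,
):
    def objective(w):
        z = A @ w
        if offset is not None:
            z = z + offset
        # log(1 + e^z) - y z, numerically stable
        loss = np.logaddexp(0.0, z) - y * z
        p = scipy.special.expit(z)
        grad = A.T @ (p - y) + l2 * w
        return loss.sum() + 0.5 * l2 * (w @ w), grad

    res = scipy.optimize.minimize(
        objective, w0, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-12},
    )
    return res.x, bool(res.success), int(res.nit)


def learn_weights(
    graph: FactorGraph,
    evidence: Mapping[str, int],
    l2: float = 0.1,
    max_iter: int = 500,
    tol: float = 1e-8,
    rng_seed: int = 0,
) -> tuple[dict[str, float], dict]:
    """Learn tied weights from evidence; returns (weights, info).

    ``info`` reports convergence and iteration counts; a non-converged fit
    is reported, not raised, and the partial weights are returned.
    """
    values = list(evidence.values())
    if not values or 1 not in values:
        raise LearningError("learning requires at least one positive evidence variable")
    if 0 not in values:
        # an all-positive evidence set is degenerate but well-posed under
        # the L2 penalty (e.g. a clean corpus with a complete seed KB)
        import logging

        logging.getLogger(__name__).warning(
            "no negative evidence; weights are determined by the L2 penalty alone"
        )
    for vid, val in evidence.items():
        graph.variables[vid].set_evidence(val)
    comp = graph.compile()

    n = len(comp.var_ids)
    x = comp.ev_val.astype(np.int8).copy()
    observed = comp.ev_mask.copy()
    rows = np.flatnonzero(comp.ev_mask)
    y = comp.ev_val[rows].astype(np.float64)

    # pass 1: unary weights from evidence neighborhoods restricted to
    # unary factors — exactly penalized logistic regression on features
    unary_mask = np.array(
        [comp.f_kind[f] == 0 for f in range(len(comp.f_kind))], dtype=bool
    )
    A1 = _build_design(comp, x, observed, rows, factor_mask=unary_mask)
    w0 = np.zeros(len(comp.weight_ids))
    w1, ok1, it1 = _fit_penalized_logistic(A1, y, l2, w0, max_iter, tol)

    # pass 2: rule weights only (aggregation, implication), with the unary
    # scores frozen as a per-row offset.  Unlabeled mention variables are
    # imputed from the unary model so that rule-factor neighborhoods are
    # fully observed; rows not touching any rule factor drop out of the
    # pass-2 objective (their likelihood does not depend on rule weights).
    ok2, it2 = True, 0
    w2 = w1.copy()
    rule_cols = np.flatnonzero(~_weight_is_unary(comp))
    if len(rule_cols) and any(k != 0 for k in comp.f_kind):
        scores = _unary_scores(comp, w1)
        x2 = x.copy()
        free = np.flatnonzero(~comp.ev_mask)
        x2[free] = (scores[free] > 0.0).astype(np.int8)
        # entity variables have no unary factors; impute them as the OR of
        # their (observed or imputed) mentions
        _impute_entities(comp, graph, x2)
        observed2 = np.ones(n, dtype=np.bool_)
        A2 = _build_design(comp, x2, observed2, rows, factor_mask=~unary_mask)
        touched = np.asarray((A2 != 0).sum(axis=1)).ravel() > 0
        if touched.any():
            A2r = A2[touched][:, rule_cols]
            offset = np.asarray(A1[touched] @ w1).ravel()
            wr, ok2, it2 = _fit_penalized_logistic(
                A2r, y[touched], l2, np.zeros(len(rule_cols)), max_iter, tol,
                offset=offset,
            )
            w2[rule_cols] = wr

    weights = {wid: float(w2[i]) for i, wid in enumerate(comp.weight_ids)}
    info = {
        "converged": bool(ok1 and ok2),
        "n_iter": int(it1 + it2),
        "n_evidence": int(len(rows)),
        "n_weights": len(weights),
    }
    return weights, info


def _unary_scores(comp: CompiledGraph, w: np.ndarray) -> np.ndarray:
    scores = np.zeros(len(comp.var_ids))
    for f in range(len(comp.f_kind)):
        if comp.f_kind[f] == 0:
            v = comp.f_vars[comp.f_ptr[f]]
            scores[v] += w[comp.f_widx[f]]
    return scores


def _impute_entities(comp: CompiledGraph, graph: FactorGraph, x: np.ndarray) -> None:
    for f in range(len(comp.f_kind)):
        if comp.f_kind[f] != 1:
            continue
        vs = comp.f_vars[comp.f_ptr[f]:comp.f_ptr[f + 1]]
        e = vs[0]
        if not comp.ev_mask[e]:
            x[e] = int(x[vs[1:]].max()) if len(vs) > 1 else 0


# --------------------------------------------------------------------------
# inference
# --------------------------------------------------------------------------

def gibbs_marginals(
    graph: FactorGraph,
    weights: Mapping[str, float] | None = None,
    evidence: Mapping[str, int] | None = None,
    n_samples: int = 20_000,
    burn_in: int | None = None,
    thin: int = 4,
    rng_seed: int = 0,
) -> MarginalTable:
    """Single-site Gibbs marginals with evidence clamped.

    Sweeps visit free variables in a fixed order; ``burn_in`` defaults to
    10% of ``n_samples``.  Each retained sample is separated by ``thin``
    sweeps, and the estimator is Rao-Blackwellised (it averages the full
    conditional P(x_v = 1 | rest) over retained sweeps), so the Monte
    Carlo error at a given sample count is well below that of the naive
    0/1 frequency.  Evidence variables report their clamped value.
    """
    from ._gibbs import gibbs_kernel

    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if burn_in is None:
        burn_in = n_samples // 10
    if evidence:
        for vid, val in evidence.items():
            graph.variables[vid].set_evidence(val)
    comp = graph.compile()
    w = comp.weight_values(weights)
    f_w = w[comp.f_widx] if len(comp.f_widx) else np.zeros(0)
    acc = gibbs_kernel(
        comp.free_vars, comp.ev_val.astype(np.int8),
        comp.f_kind, f_w.astype(np.float64), comp.f_ptr, comp.f_vars,
        comp.v_ptr, comp.v_facs,
        int(n_samples), int(burn_in), max(1, int(thin)), int(rng_seed) % (2**31),
    )
    probs = {
        vid: (float(comp.ev_val[i]) if comp.ev_mask[i] else float(acc[i]))
        for i, vid in enumerate(comp.var_ids)
    }
    return MarginalTable(probs, n_samples, burn_in, rng_seed)


def exact_marginals(
    graph: FactorGraph,
    weights: Mapping[str, float] | None = None,
    evidence: Mapping[str, int] | None = None,
    max_free: int = 20,
) -> MarginalTable:
    """Marginals by full enumeration of the free variables (<= ``max_free``)."""
    if evidence:
        for vid, val in evidence.items():
            graph.variables[vid].set_evidence(val)
    comp = graph.compile()
    free = comp.free_vars
    k = len(free)
    if k > max_free:
        raise ValueError(f"{k} free variables exceed enumeration limit {max_free}")
    w = comp.weight_values(weights)

    n_assign = 1 << k
    idx = np.arange(n_assign, dtype=np.int64)
    bit_of = {int(v): i for i, v in enumerate(free)}

    def values(v: int) -> np.ndarray:
        if comp.ev_mask[v]:
            return np.full(n_assign, int(comp.ev_val[v]), dtype=np.int8)
        return ((idx >> bit_of[v]) & 1).astype(np.int8)

    logw = np.zeros(n_assign)
    for f in range(len(comp.f_kind)):
        wf = w[comp.f_widx[f]]
        vs = comp.f_vars[comp.f_ptr[f]:comp.f_ptr[f + 1]]
        kind = comp.f_kind[f]
        if kind == 0:
            logw += wf * values(int(vs[0]))
        elif kind == 2:
            a, b = (values(int(u)) for u in vs)
            logw += wf * ((a == 0) | (b == 1))
        else:
            e = values(int(vs[0]))
            mx = np.zeros(n_assign, dtype=np.int8)
            for u in vs[1:]:
                np.maximum(mx, values(int(u)), out=mx)
            logw += wf * (e == mx)

    logz = scipy.special.logsumexp(logw)
    probs: dict[str, float] = {}
    for i, vid in enumerate(comp.var_ids):
        if comp.ev_mask[i]:
            probs[vid] = float(comp.ev_val[i])
        else:
            sel = values(i).astype(bool)
            probs[vid] = (
                float(np.exp(scipy.special.logsumexp(logw[sel]) - logz))
                if sel.any() else 0.0
            )
    return MarginalTable(probs, n_samples=0, burn_in=0, rng_seed=None)


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

def isotonic_calibrator(
    probs: Sequence[float], labels: Sequence[int], min_block: int = 50
):
    """Fit a monotone map from raw marginals to empirical frequencies.

    Pool-adjacent-violators on (probability, label) pairs; the returned
    callable maps new probabilities by step-function lookup (left-
    continuous, clipped to [0, 1]).  Used to recalibrate marginals against
    held-out assessed variables.  Consecutive sorted samples are pooled
    into blocks of at least ``min_block`` before PAVA so that every step
    of the fitted map rests on a stable empirical frequency.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.size == 0:
        return lambda q: np.asarray(q, dtype=float)
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    y_sorted = y[order]
    # group by unique probability value first (candidates with identical
    # feature sets share an exact score and form one homogeneous class),
    # then merge adjacent groups until each block carries >= min_block
    uniq, first_idx, counts = np.unique(
        np.round(p_sorted, 9), return_index=True, return_counts=True
    )
    means, weights, starts = [], [], []
    for u_i in range(len(uniq)):
        lo = int(first_idx[u_i])
        cnt = int(counts[u_i])
        m = float(y_sorted[lo:lo + cnt].mean())
        if means and weights[-1] < min_block:
            w_old = weights[-1]
            means[-1] = (means[-1] * w_old + m * cnt) / (w_old + cnt)
            weights[-1] += cnt
        else:
            means.append(m)
            weights.append(float(cnt))
            starts.append(lo)
    # a short final block folds backwards
    if len(means) > 1 and weights[-1] < min_block:
        m2, w2 = means.pop(), weights.pop()
        starts.pop()
        means[-1] = (means[-1] * weights[-1] + m2 * w2) / (weights[-1] + w2)
        weights[-1] += w2
    starts = [int(s) for s in starts]
    i = 0
    merged_means: list[float] = []
    merged_weights: list[float] = []
    merged_starts: list[int] = []
    for m, w, s in zip(means, weights, starts):
        merged_means.append(m)
        merged_weights.append(w)
        merged_starts.append(s)
        while (
            len(merged_means) > 1 and merged_means[-2] >= merged_means[-1]
        ):
            m2 = merged_means.pop()
            w2 = merged_weights.pop()
            merged_starts.pop()
            merged_means[-1] = (
                merged_means[-1] * merged_weights[-1] + m2 * w2
            ) / (merged_weights[-1] + w2)
            merged_weights[-1] += w2
    block_lo = p_sorted[np.array(merged_starts)]
    block_val = np.clip(np.array(merged_means), 0.0, 1.0)

    def apply(q):
        q = np.asarray(q, dtype=float)
        idx = np.searchsorted(block_lo, q, side="right") - 1
        idx = np.clip(idx, 0, len(block_val) - 1)
        return block_val[idx]

    return apply

def calibration_table(
    marginals: Mapping[str, float],
    gold_labels: Mapping[str, int],
    n_bins: int = 10,
) -> list[CalibrationBin]:
    """Reliability table: equal-width probability bins vs empirical accuracy.

    Every scored variable must have a gold label; a prediction of exactly
    1.0 falls in the top bin.
    """
    missing = set(marginals) - set(gold_labels)
    if missing:
        raise KeyError(f"{len(missing)} scored variables lack gold labels")
    counts = np.zeros(n_bins, dtype=int)
    correct = np.zeros(n_bins, dtype=int)
    for vid, p in marginals.items():
        b = min(int(p * n_bins), n_bins - 1)
        counts[b] += 1
        correct[b] += int(gold_labels[vid])
    return [
        CalibrationBin(i / n_bins, (i + 1) / n_bins, int(counts[i]), int(correct[i]))
        for i in range(n_bins)
    ]
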