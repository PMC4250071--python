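import numpy as np
import pytest

from stratmine.corpus import WorldConfig, generate_world
from stratmine.graph import FactorGraph, Variable
from stratmine.timescale import default_interval_table


@pytest.fixture(scope="session")
def table():
    return default_interval_table()


@pytest.fixture(scope="session")
def small_world(table):
    """A modest noisy world shared by extraction-level tests."""
    cfg = WorldConfig(
        n_formations=12, n_taxa=40, n_documents=30, rng_seed=7,
        distractor_rate=0.3, synonym_usage_rate=0.2,
    )
    return generate_world(cfg, table)


@pytest.fixture(scope="session")
def clean_world(table):
    """Zero corruption, zero distractors: every fact exactly recoverable."""
    cfg = WorldConfig(
        n_formations=10, n_taxa=30, n_documents=20, rng_seed=3,
        corruption_rate=0.0, distractor_rate=0.0, synonym_usage_rate=0.2,
        seed_kb_fraction=1.0,
    )
    return generate_world(cfg, table)


def make_random_graph(rng: np.random.Generator, max_vars: int = 13) -> FactorGraph:
    """Random small factor graph with mixed factor kinds, weights in [-2, 2]."""
    g = FactorGraph()
    n = int(rng.integers(3, max_vars))
    ids = [f"v{i}" for i in range(n)]
    for vid in ids:
        g.add_variable(Variable(vid, "mention_relation"))
    weights = {}
    for k in range(int(rng.integers(n, 3 * n))):
        kind = rng.choice(
            ["unary_feature", "implication", "aggregation"], p=[0.5, 0.3, 0.2]
        )
        wid = f"w{k}"
        weights[wid] = float(rng.uniform(-2, 2))
        if kind == "unary_feature":
            g.add_factor(kind, [str(rng.choice(ids))], wid)
        elif kind == "implication":
            a, b = rng.choice(ids, size=2, replace=False)
            g.add_factor(kind, [str(a), str(b)], wid)
        else:
            m = int(rng.integers(1, min(4, n)))
            vs = rng.choice(ids, size=m + 1, replace=False)
            g.add_factor(kind, [str(v) for v in vs], wid)
    g.set_weights(weights)
    return g
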