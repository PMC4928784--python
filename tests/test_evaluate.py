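"""Validation statistics: W, R, weights, depths, diversity indices,
coverage, and the bootstrap retention experiment."""

import math

import networkx as nx
import numpy as np
import pytest

from ploidytree import (
    ContractError,
    Dataset,
    MutationFrequencies,
    ProbePanel,
    ProgressionTree,
    avg_edge_weight,
    coverage,
    expected_depth,
    reconstruction_error,
    reweight_edges,
    shannon_entropy,
    simpson_index,
    state_retention_bootstrap,
    steiner_fraction,
    tree_event_distribution,
    tree_weight,
    w_statistic,
)


@pytest.fixture
def panel():
    return ProbePanel("ploidy", ("g",))


def _chain(panel, states, probs=None, observed=None):
    t = ProgressionTree(panel)
    first = states[0]
    t.add_node(first, observed=True, frequency=1)
    for k in range(1, len(states)):
        obs = observed[k] if observed else True
        t.add_node(states[k], observed=obs, frequency=1)
        t.add_edge(states[k - 1], states[k], None,
                   probs[k - 1] if probs else 0.5)
    return t


# -- W -------------------------------------------------------------------

def test_w_statistic_values():
    assert w_statistic({(0, 1): 0.4, (0, -1): 0.6},
                       {(0, 1): 0.4, (0, -1): 0.6}) == 0.0
    w = w_statistic({(0, 1): 0.5, (0, -1): 0.5},
                    {(0, 1): 0.25, (0, -1): 0.75})
    assert w == pytest.approx(0.25 + 0.0625 / 0.75, abs=1e-12)


def test_w_statistic_requires_positive_actual():
    with pytest.raises(ContractError):
        w_statistic({(0, 1): 1.0}, {(0, 1): 0.5, (0, -1): 0.0})


# -- R -------------------------------------------------------------------

def test_r_is_zero_for_identical_trees(panel):
    t = _chain(panel, [(2, 2), (2, 3), (2, 4), (3, 4)])
    assert reconstruction_error(t, t) == 0.0


def test_r_is_hundred_for_disjoint_trees(panel):
    a = _chain(panel, [(2, 2), (2, 3)])
    b = _chain(panel, [(2, 2), (3, 2)])
    assert reconstruction_error(a, b) == 100.0


def test_r_chain_swap_matches_brute_force_matching(panel):
    """4-state chain vs the same chain with the last two states'
    parents swapped, scored against an independent maximum-weight
    matching over all bipartition pairs."""
    a = _chain(panel, [(2, 2), (2, 3), (2, 4), (2, 5)])
    b = ProgressionTree(panel)
    b.add_node((2, 2), observed=True, frequency=1)
    for s in [(2, 3), (2, 4), (2, 5)]:
        b.add_node(s, observed=True, frequency=1)
    b.add_edge((2, 2), (2, 3), None, 0.5)
    b.add_edge((2, 3), (2, 5), None, 0.5)   # swapped attachment
    b.add_edge((2, 3), (2, 4), None, 0.5)

    def bips(t):
        return [frozenset(t.subtree(c)) for _, c, _ in t.edges()]

    shared = frozenset(a.nodes()) & frozenset(b.nodes()) - {a.root}

    def sim(x, y):
        s, g = x & shared, y & shared
        if not (s | g):
            return 0.0
        return (len(s & g) + len(shared) - len(s | g)) / len(shared)

    g = nx.Graph()
    pa, pb = bips(a), bips(b)
    for i, x in enumerate(pa):
        for j, y in enumerate(pb):
            g.add_edge(("a", i), ("b", j), weight=sim(x, y))
    match = nx.max_weight_matching(g)
    m = sum(g.edges[e]["weight"] for e in match)
    expected = (1 - m / (len(pa) + len(pb) - m)) * 100
    assert reconstruction_error(a, b) == pytest.approx(expected, abs=1e-9)


def test_r_range_and_asymmetric_sizes(panel, rng):
    from ploidytree import SimulationConfig, rate_set, simulate_tree

    cfg = SimulationConfig(rates=rate_set("dataset1"), n_trees=1,
                           nodes_per_tree=12)
    for _ in range(5):
        a = simulate_tree(cfg, rng)
        b = simulate_tree(cfg, rng)
        r = reconstruction_error(a, b)
        assert 0.0 <= r <= 100.0
        assert reconstruction_error(a, b) == pytest.approx(
            reconstruction_error(b, a)
        )


# -- weights -------------------------------------------------------------

def test_tree_weight_and_average(panel):
    t = _chain(panel, [(2, 2), (2, 3), (2, 4), (2, 5)],
               probs=[1 / math.e] * 3)
    assert tree_weight(t) == pytest.approx(3.0, abs=1e-12)
    assert avg_edge_weight(t) == pytest.approx(1.0, abs=1e-12)
    sure = _chain(panel, [(2, 2), (2, 3)], probs=[1.0])
    assert tree_weight(sure) == 0.0
    assert tree_weight(t) == pytest.approx(avg_edge_weight(t) * t.n_edges)


def test_avg_edge_weight_approaches_entropy_of_edge_distribution(panel, rng):
    """When edges are reweighted by the tree's own event distribution,
    the average edge weight is exactly that distribution's entropy."""
    from ploidytree import SimulationConfig, rate_set, simulate_tree

    cfg = SimulationConfig(rates=rate_set("dataset3"), n_trees=1,
                           nodes_per_tree=30)
    t = simulate_tree(cfg, rng)
    dist = tree_event_distribution(t)
    w = reweight_edges(t, dist)
    assert avg_edge_weight(w) == pytest.approx(shannon_entropy(dist), abs=1e-9)


# -- depth, entropy, Simpson ---------------------------------------------

def test_expected_depth(panel):
    t = _chain(panel, [(2, 2), (2, 3), (2, 4)])
    ds = Dataset(panel, {(2, 2): 10, (2, 3): 20, (2, 4): 30})
    assert expected_depth(t, ds) == pytest.approx(4 / 3)
    all_root = Dataset(panel, {(2, 2): 50})
    assert expected_depth(t, all_root) == 0.0
    half = Dataset(panel, {(2, 2): 25, (2, 3): 25})
    assert expected_depth(t, half) == 0.5
    with pytest.raises(ContractError):
        expected_depth(t, Dataset(panel, {(3, 3): 5}))


def test_entropy_and_simpson_values():
    uniform8 = {ev: 1 / 8 for ev in range(8)}
    assert shannon_entropy(uniform8) == pytest.approx(math.log(8))
    assert simpson_index(uniform8) == pytest.approx(0.125)
    point = {0: 1.0, 1: 0.0}
    assert shannon_entropy(point) == 0.0
    assert simpson_index(point) == 1.0
    mixed = {0: 0.5, 1: 0.25, 2: 0.25}
    assert shannon_entropy(mixed) == pytest.approx(1.5 * math.log(2))
    assert simpson_index(mixed) == pytest.approx(0.375)


def test_entropy_and_simpson_move_oppositely_under_majorization(rng):
    """If p majorizes q (p is more concentrated), then SE(p) <= SE(q)
    and SI(p) >= SI(q)."""
    checked = 0
    while checked < 20:
        p = np.sort(rng.dirichlet(np.ones(6)))[::-1]
        q = np.sort(rng.dirichlet(np.ones(6)))[::-1]
        if np.all(np.cumsum(p) >= np.cumsum(q) - 1e-12):
            dp = {k: v for k, v in enumerate(p)}
            dq = {k: v for k, v in enumerate(q)}
            assert shannon_entropy(dp) <= shannon_entropy(dq) + 1e-9
            assert simpson_index(dp) >= simpson_index(dq) - 1e-9
            checked += 1


# -- coverage, Steiner fraction, bootstrap --------------------------------

def test_coverage_and_steiner_fraction(panel):
    t = _chain(panel, [(2, 2), (2, 3), (2, 4)],
               observed=[True, False, True])
    ds_full = Dataset(panel, {(2, 2): 5, (2, 4): 5})
    assert coverage(t, ds_full) == 1.0
    ds4 = Dataset(panel, {(2, 2): 1, (2, 4): 1, (3, 3): 1, (5, 5): 1})
    assert coverage(t, ds4) == 0.5
    root_only = ProgressionTree(panel)
    assert coverage(root_only, ds4) == 0.25
    assert steiner_fraction(t) == pytest.approx(1 / 3)


def test_bootstrap_single_pattern_and_determinism(panel):
    ds = Dataset(panel, {(2, 3): 40})
    assert state_retention_bootstrap(ds, 10, np.random.default_rng(0)) == 1.0
    ds2 = Dataset(panel, {(2, 2): 10, (2, 3): 1, (3, 3): 1})
    a = state_retention_bootstrap(ds2, 50, np.random.default_rng(4))
    b = state_retention_bootstrap(ds2, 50, np.random.default_rng(4))
    assert a == b


def test_bootstrap_matches_closed_form_for_uniform_patterns(panel):
    """Uniform over N patterns with n cells: expected retention is
    1 - (1 - 1/N)^n per pattern."""
    n_patterns, per = 8, 4
    states = [(2, g) for g in range(n_patterns)]
    ds = Dataset(panel, {s: per for s in states})
    n = ds.total_cells
    expected = 1 - (1 - 1 / n_patterns) ** n
    got = state_retention_bootstrap(ds, 400, np.random.default_rng(11))
    assert got == pytest.approx(expected, abs=0.02)
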