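"""Graph construction, Steiner insertion, branchings (vs brute force),
randomized branchings, and the single-gene EM."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from ploidytree import (
    ContractError,
    Dataset,
    EMConfig,
    MutationFrequencies,
    ProbePanel,
    allowed_event_types,
    allowed_transitions,
    build_observed_graph,
    build_possible_graph,
    fit_single_gene_tree,
    insert_steiner_nodes,
    max_weight_branching,
    randomize_branching,
)
from ploidytree.single_gene import branching_weight
from conftest import make_random_dataset


def brute_force_min_arborescence(g, root):
    """Exhaustive minimum-weight spanning arborescence: every non-root
    node picks one in-edge; keep acyclic assignments."""
    nodes = [n for n in g.nodes if n != root]
    choices = []
    for n in nodes:
        preds = list(g.predecessors(n))
        assert preds, f"node {n} has no candidate parent"
        choices.append([(p, n) for p in preds])
    best, best_w = None, np.inf
    for combo in itertools.product(*choices):
        h = nx.DiGraph()
        h.add_nodes_from(g.nodes)
        h.add_edges_from(combo)
        if not nx.is_arborescence(h):
            continue
        w = sum(g.edges[e]["weight"] for e in combo)
        if w < best_w:
            best_w, best = w, combo
    return best, best_w


# -- graphs --------------------------------------------------------------

def test_possible_graph_node_counts():
    assert build_possible_graph(ProbePanel("p", ("g",))).number_of_nodes() == 90
    small = build_possible_graph(ProbePanel("p", ("g",), max_copy=2))
    assert small.number_of_nodes() == 6
    # edge count against independent enumeration of allowed deltas
    expected = 0
    for p in range(1, 3):
        for g in range(0, 3):
            expected += len(allowed_transitions((p, g), 2))
    assert small.number_of_edges() == expected
    for u, v, data in small.edges(data=True):
        assert tuple(b - a for a, b in zip(u, v)) == data["event"]
        assert data["event"] in allowed_event_types(1)


@pytest.mark.parametrize(
    "counts,n_nodes,n_edges",
    [
        ({(2, 2): 100}, 1, 0),
        ({(2, 2): 50, (2, 3): 50}, 2, 2),   # gain and loss edges
        ({(2, 4): 10}, 2, 0),               # root added, not adjacent
    ],
)
def test_observed_graph(single_panel, counts, n_nodes, n_edges):
    ds = Dataset(single_panel, counts)
    g = build_observed_graph(ds)
    assert g.number_of_nodes() == n_nodes
    assert g.number_of_edges() == n_edges


# -- Steiner insertion ---------------------------------------------------

@pytest.mark.parametrize(
    "observed,expected_steiner",
    [
        ({(2, 2): 1, (2, 4): 1}, {(2, 3)}),
        ({(2, 2): 1, (2, 3): 1}, set()),
        ({(2, 2): 1, (4, 4): 1}, {(3, 3)}),
    ],
)
def test_steiner_insertion_known_paths(single_panel, observed, expected_steiner):
    """(2,2)->(2,3)->(2,4) is the unique shortest route under uniform
    frequencies; the diagonal through (3,3) is invalid because (-1,+1)
    is not an allowed event."""
    ds = Dataset(single_panel, observed)
    freqs = MutationFrequencies.uniform(allowed_event_types(1))
    g = insert_steiner_nodes(build_observed_graph(ds), freqs, single_panel)
    steiner = {n for n, d in g.nodes(data=True) if not d["observed"]}
    steiner -= {single_panel.root} if single_panel.root not in observed else set()
    assert steiner == expected_steiner


def test_all_observed_reachable_after_insertion(single_panel, rng):
    freqs = MutationFrequencies.uniform(allowed_event_types(1))
    for _ in range(20):
        ds = make_random_dataset(single_panel, rng, n_patterns=7)
        g = insert_steiner_nodes(build_observed_graph(ds), freqs, single_panel)
        reachable = {single_panel.root} | nx.descendants(g, single_panel.root)
        assert set(ds.patterns) <= reachable


# -- maximum-weight branching --------------------------------------------

def test_branching_on_a_tree_returns_it(single_panel):
    freqs = MutationFrequencies.uniform(allowed_event_types(1))
    g = nx.DiGraph()
    for n in [(2, 2), (2, 3), (3, 3)]:
        g.add_node(n, observed=True, frequency=1)
    g.add_edge((2, 2), (2, 3), event=(0, 1))
    g.add_edge((2, 3), (3, 3), event=(1, 0))
    tree = max_weight_branching(g, freqs, single_panel)
    assert tree.parent((2, 3)) == (2, 2)
    assert tree.parent((3, 3)) == (2, 3)


def test_branching_matches_brute_force_on_random_graphs(single_panel, rng):
    """Edmonds output equals exhaustive enumeration on graphs of up to
    6 nodes with random edge weights."""
    possible = build_possible_graph(ProbePanel("p", ("g",), max_copy=4))
    nodes_all = sorted(possible.nodes)
    for _ in range(60):
        root = (2, 2)
        k = int(rng.integers(3, 7))
        chosen = {root}
        while len(chosen) < k:
            chosen.add(nodes_all[rng.integers(len(nodes_all))])
        g = possible.subgraph(chosen).copy()
        reachable = {root} | nx.descendants(g, root)
        g = g.subgraph(reachable).copy()
        if g.number_of_nodes() < 2:
            continue
        for u, v in g.edges:
            g.edges[u, v]["weight"] = float(rng.uniform(0.1, 3.0))
        for n in g.nodes:
            g.nodes[n].setdefault("observed", True)
            g.nodes[n].setdefault("frequency", 1)
        h = g.copy()
        h.remove_edges_from(list(h.in_edges(root)))
        _, brute_w = brute_force_min_arborescence(h, root)
        tree = max_weight_branching(g, None, single_panel)
        got_w = sum(
            -math.log(e.probability) for _, _, e in tree.edges()
        )
        assert got_w == pytest.approx(brute_w, abs=1e-6)


def test_branching_diamond_matches_brute_force(single_panel):
    """Diamond with p(gene gain)=0.5, p(ploidy gain)=0.1, p(both)=0.2:
    the optimal parent of (3,3) agrees with exhaustive search."""
    probs = {(0, 1): 0.5, (1, 0): 0.1, (1, 1): 0.2, (0, -1): 0.1,
             (-1, 0): 0.05, (-1, -1): 0.05}
    freqs = MutationFrequencies(probs)
    g = nx.DiGraph()
    for n in [(2, 2), (2, 3), (3, 2), (3, 3)]:
        g.add_node(n, observed=True, frequency=1)
    for u, v in [((2, 2), (2, 3)), ((2, 2), (3, 2)), ((2, 2), (3, 3)),
                 ((2, 3), (3, 3)), ((3, 2), (3, 3))]:
        ev = tuple(b - a for a, b in zip(u, v))
        g.add_edge(u, v, event=ev, weight=freqs.weight(ev))
    h = g.copy()
    h.remove_edges_from(list(h.in_edges((2, 2))))
    combo, brute_w = brute_force_min_arborescence(h, (2, 2))
    tree = max_weight_branching(g, freqs, single_panel)
    assert branching_weight(tree, freqs) == pytest.approx(brute_w, abs=1e-6)
    brute_parent = {c: p for p, c in combo}
    assert tree.parent((3, 3)) == brute_parent[(3, 3)]


def test_unreachable_node_is_a_contract_error(single_panel):
    freqs = MutationFrequencies.uniform(allowed_event_types(1))
    g = nx.DiGraph()
    g.add_node((2, 2), observed=True, frequency=1)
    g.add_node((2, 5), observed=True, frequency=1)
    with pytest.raises(ContractError):
        max_weight_branching(g, freqs, single_panel)


# -- randomized branching ------------------------------------------------

def _fitted_graph_and_tree(single_panel, rng):
    ds = make_random_dataset(single_panel, rng, n_patterns=8)
    freqs = MutationFrequencies.uniform(allowed_event_types(1))
    g = insert_steiner_nodes(build_observed_graph(ds), freqs, single_panel)
    return g, max_weight_branching(g, freqs, single_panel), freqs


def test_randomize_eps_zero_is_identity(single_panel, rng):
    g, tree, freqs = _fitted_graph_and_tree(single_panel, rng)
    assert randomize_branching(tree, g, freqs, rng, 0.0) is tree


def test_randomize_preserves_tree_invariants(single_panel, rng):
    g, tree, freqs = _fitted_graph_and_tree(single_panel, rng)
    for _ in range(200):
        out = randomize_branching(tree, g, freqs, rng, 0.5)
        out.validate()
        assert set(out.nodes()) == set(tree.nodes())


def test_randomize_is_deterministic_under_fixed_seed(single_panel):
    rng = np.random.default_rng(7)
    g, tree, freqs = _fitted_graph_and_tree(single_panel, rng)
    a = randomize_branching(tree, g, freqs, np.random.default_rng(99), 0.5)
    b = randomize_branching(tree, g, freqs, np.random.default_rng(99), 0.5)
    assert a == b


# -- EM ------------------------------------------------------------------

def test_fit_root_only_dataset(single_panel, rng):
    ds = Dataset(single_panel, {(2, 2): 100})
    tree, freqs = fit_single_gene_tree(ds, single_panel, "g", rng=rng)
    assert tree.n_nodes == 1 and tree.n_edges == 0
    assert all(math.isclose(p, 1 / 6) for p in freqs.probs.values())


def test_fit_single_edge_fixed_point(single_panel, rng):
    """With one observed gain and no randomization the EM concentrates
    the gene-gain frequency up to the probability floor."""
    ds = Dataset(single_panel, {(2, 2): 50, (2, 3): 50})
    tree, freqs = fit_single_gene_tree(
        ds, single_panel, "g", EMConfig(eps=0.0), rng
    )
    assert tree.parent((2, 3)) == (2, 2)
    assert freqs.prob((0, 1)) == pytest.approx(1.0 - 5e-6, abs=1e-7)


def test_fit_recovers_simulated_frequencies(single_panel):
    """Parameter recovery: single-gene samples simulated from known
    rates are estimated within total-variation 0.15 on average."""
    from ploidytree import SimulationConfig, simulate_instance

    truth = MutationFrequencies(
        {(0, 1): 0.40, (0, -1): 0.20, (1, 1): 0.20, (-1, -1): 0.05,
         (1, 0): 0.10, (-1, 0): 0.05}
    )
    from ploidytree import tree_event_distribution

    cfg = SimulationConfig(
        rates=truth, n_trees=1, nodes_per_tree=20, cells_per_sample=500
    )
    tvs = []
    pooled_est: dict = {}
    pooled_true: dict = {}
    seeds = np.random.SeedSequence(2024).spawn(20)
    for s in seeds:
        r = np.random.default_rng(s)
        inst = simulate_instance(cfg, r)
        tree, est = fit_single_gene_tree(inst.dataset, cfg.panel, "g1", rng=r)
        tvs.append(est.tv_distance(inst.realized_rates))
        for _, _, e in tree.edges():
            for ev in e.events:
                pooled_est[ev] = pooled_est.get(ev, 0.0) + 1.0
        for _, _, e in inst.true_tree.edges():
            for ev in e.events:
                pooled_true[ev] = pooled_true.get(ev, 0.0) + 1.0
    evs = allowed_event_types(1)
    pooled_tv = MutationFrequencies.from_tallies(pooled_est, evs, 0.0).tv_distance(
        MutationFrequencies.from_tallies(pooled_true, evs, 0.0)
    )
    # pooled recovery is tight; per-replicate estimates carry the
    # sampling noise of a single ~20-edge tree
    assert pooled_tv < 0.15
    assert np.mean(tvs) < 0.40


def test_fit_covers_every_observed_pattern(single_panel, rng):
    for _ in range(5):
        ds = make_random_dataset(single_panel, rng, n_patterns=9)
        tree, _ = fit_single_gene_tree(ds, single_panel, "g", rng=rng)
        for pat in ds.patterns:
            assert pat in tree and not tree.is_steiner(pat)


def test_fit_is_deterministic_given_seed(single_panel):
    rng = np.random.default_rng(31)
    ds = make_random_dataset(single_panel, rng, n_patterns=8)
    t1, f1 = fit_single_gene_tree(ds, single_panel, "g",
                                  rng=np.random.default_rng(5))
    t2, f2 = fit_single_gene_tree(ds, single_panel, "g",
                                  rng=np.random.default_rng(5))
    assert t1 == t2 and f1.probs == f2.probs
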