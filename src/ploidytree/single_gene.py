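"""Single-gene progression trees: graph construction, Steiner-node
insertion, maximum-weight branchings, and EM estimation of event
frequencies.

For each gene probe the sample is marginalized to the pair
``(ploidy, gene)`` and a rooted tree over the observed ``(p, g)`` states
is inferred:

1. build the graph of observed states plus the diploid root, with every
   allowed transition between included states as a candidate edge;
2. insert unobserved (Steiner) intermediate states along minimum-weight
   paths so that every observed state is reachable from the root;
3. find a maximum-weight branching (rooted spanning arborescence) where
   an edge of event probability ``p`` has weight ``log p``; and
4. run EM: re-estimate event frequencies from the clonal-frequency
   weighted edge tallies of a randomly perturbed branching (each edge is
   evidenced by every cell in the subtree below it), and repeat until
   the frequencies stabilize, keeping the best-scoring branching seen.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import networkx as nx
import numpy as np

from .datamodel import Dataset, Pattern, ProbePanel, ProgressionTree
from .errors import ContractError
from .events import (
    MutationFrequencies,
    allowed_event_types,
    allowed_transitions,
    DEFAULT_FLOOR,
)

#: deterministic tie-break perturbation added to edge weights, scaled by
#: the lexicographic rank of the edge; far below any real weight gap
_TIE_EPS = 1e-12


@dataclass
class EMConfig:
    """Tunables of the EM loop.

    eps is the per-node perturbation probability of the randomized
    branching step; tol the L-infinity convergence threshold on the
    event frequencies; the floor keeps every event probability positive.
    """

    eps: float = 0.05
    tol: float = 1e-6
    max_iters: int = 40
    restarts: int = 2
    floor: float = DEFAULT_FLOOR
    tally_weighting: str = "clonal"  # "clonal", "cells", or "edges"
    retention: str = "best"  # "best" (min weight) or "final" (converged)
    init: str = "observed"   # "observed" (adjacency tallies) or "uniform"
    resteiner: bool = False  # re-run Steiner insertion with current freqs
    augment_paths: bool = False  # insert likelier multi-step Steiner routes


def build_possible_graph(panel: ProbePanel) -> nx.DiGraph:
    """Graph of *all* in-bound copy-number states of the panel with every
    allowed transition as an edge (the search space for Steiner paths)."""
    g = nx.DiGraph()
    cap = panel.max_copy
    ranges = [range(1, cap + 1)] + [range(0, cap + 1)] * panel.n_genes
    for state in itertools.product(*ranges):
        g.add_node(state)
    for state in list(g.nodes):
        for succ, delta in allowed_transitions(state, panel):
            g.add_edge(state, succ, event=delta)
    return g


def build_observed_graph(ds: Dataset) -> nx.DiGraph:
    """Graph over the observed patterns plus the diploid root, with all
    allowed transitions between included states."""
    panel = ds.panel
    g = nx.DiGraph()
    g.add_node(panel.root, observed=panel.root in ds.counts,
               frequency=ds.frequency(panel.root))
    for pat in ds.patterns:
        g.add_node(pat, observed=True, frequency=ds.counts[pat])
    _induce_allowed_edges(g, panel)
    return g


def _induce_allowed_edges(g: nx.DiGraph, panel: ProbePanel) -> None:
    nodes = set(g.nodes)
    for state in sorted(nodes):
        for succ, delta in allowed_transitions(state, panel):
            if succ in nodes:
                g.add_edge(state, succ, event=delta)


def insert_steiner_nodes(
    g: nx.DiGraph,
    freqs: MutationFrequencies,
    panel: ProbePanel,
    possible: Optional[nx.DiGraph] = None,
) -> nx.DiGraph:
    """Add unobserved intermediate states until every observed state is
    reachable from the root.

    Unreachable states are connected through minimum-weight (``-log p``)
    directed paths in the graph of all possible states, starting from the
    currently reachable set; targets are processed in order of increasing
    path weight with lexicographic ties.  Added states are flagged as
    Steiner (``observed=False``).
    """
    out = g.copy()
    if possible is None:
        possible = build_possible_graph(panel)
    weight = {delta: freqs.weight(delta) for delta in allowed_event_types(panel.n_genes)}

    def wfun(u, v, data):
        return weight[data["event"]]

    root = panel.root
    while True:
        reachable = {root} | nx.descendants(out, root)
        missing = sorted(n for n in out.nodes if n not in reachable)
        if not missing:
            break
        dist, paths = nx.multi_source_dijkstra(possible, reachable, weight=wfun)
        target = min(missing, key=lambda n: (dist[n], n))
        for node in paths[target]:
            if node not in out:
                out.add_node(node, observed=False, frequency=0)
        _induce_allowed_edges(out, panel)
    return out


def augment_likely_paths(
    g: nx.DiGraph,
    freqs: MutationFrequencies,
    panel: ProbePanel,
    possible: Optional[nx.DiGraph] = None,
) -> nx.DiGraph:
    """Insert Steiner intermediates wherever a multi-step path of likely
    events is cheaper than a node's best direct in-edge.

    A rare event (say a concerted loss) connecting two states can be
    less probable than a chain of common events through unobserved
    intermediates; this pass adds those intermediates so the branching
    may choose the likelier route.
    """
    out = g.copy()
    if possible is None:
        possible = build_possible_graph(panel)
    weight = {
        delta: freqs.weight(delta)
        for delta in allowed_event_types(panel.n_genes)
    }

    def wfun(u, v, data):
        return weight[data["event"]]

    root = panel.root
    while True:
        added_any = False
        for v in sorted(out.nodes):
            if v == root:
                continue
            direct = [
                weight[out.edges[u, v]["event"]] for u in out.predecessors(v)
            ]
            best_direct = min(direct) if direct else np.inf
            sources = set(out.nodes) - {v}
            try:
                dist, path = nx.multi_source_dijkstra(
                    possible, sources, target=v, weight=wfun
                )
            except nx.NetworkXNoPath:  # cannot happen: space is connected
                continue
            if dist < best_direct - 1e-12:
                new_nodes = [n for n in path[1:-1] if n not in out]
                for n in new_nodes:
                    out.add_node(n, observed=False, frequency=0)
                    added_any = True
        if not added_any:
            break
        _induce_allowed_edges(out, panel)
    return out


def _apply_weights(g: nx.DiGraph, freqs: MutationFrequencies) -> None:
    # lexicographic rank perturbation keeps Edmonds' output deterministic
    for rank, (u, v) in enumerate(sorted(g.edges)):
        g.edges[u, v]["weight"] = freqs.weight(g.edges[u, v]["event"]) + rank * _TIE_EPS


def max_weight_branching(
    g: nx.DiGraph,
    freqs: Optional[MutationFrequencies] = None,
    panel: Optional[ProbePanel] = None,
    root: Optional[Pattern] = None,
) -> ProgressionTree:
    """Spanning arborescence rooted at the diploid state maximizing the
    sum of ``log p`` over edges (equivalently minimizing total
    ``-log p``), via Edmonds' algorithm.

    If ``freqs`` is given, edge weights are derived from it; otherwise
    each edge must already carry a ``weight`` attribute.
    """
    if panel is None:
        some = next(iter(g.nodes))
        panel = ProbePanel("p", tuple(f"g{i}" for i in range(len(some) - 1)))
    if root is None:
        root = panel.root
    h = g.copy()
    if freqs is not None:
        _apply_weights(h, freqs)
    reachable = {root} | nx.descendants(h, root)
    if set(h.nodes) - reachable:
        raise ContractError(
            f"nodes unreachable from root: {sorted(set(h.nodes) - reachable)}"
            " (run insert_steiner_nodes first)"
        )
    h.remove_edges_from(list(h.in_edges(root)))
    if h.number_of_nodes() == 1:
        arb = h
    else:
        arb = nx.minimum_spanning_arborescence(h, attr="weight", preserve_attrs=True)

    tree = ProgressionTree(panel)
    for node in arb.nodes:
        data = g.nodes[node]
        tree.add_node(node, data.get("observed", False), data.get("frequency", 0))
    for u, v, data in arb.edges(data=True):
        ev = data["event"]
        prob = freqs.prob(ev) if freqs is not None else float(np.exp(-data["weight"]))
        tree.add_edge(u, v, (ev,), prob)
    return tree


def randomize_branching(
    tree: ProgressionTree,
    g: nx.DiGraph,
    freqs: MutationFrequencies,
    rng: np.random.Generator,
    eps: float,
) -> ProgressionTree:
    """Randomly perturb a branching: each non-root node's parent is, with
    probability ``eps``, resampled among its in-neighbors in ``g``
    proportionally to the event probability; any cycle created is
    repaired by reverting perturbed nodes (lexicographically smallest
    first) to their original parents.
    """
    if eps <= 0:
        return tree
    root = tree.root
    original = {chi: par for par, chi, _ in tree.edges()}
    parents = dict(original)
    perturbed = set()
    for node in sorted(parents):
        if rng.random() >= eps:
            continue
        cands = sorted(u for u in g.predecessors(node) if u in tree)
        if not cands:
            continue
        probs = np.array([freqs.prob(g.edges[u, node]["event"]) for u in cands])
        choice = cands[rng.choice(len(cands), p=probs / probs.sum())]
        if choice != parents[node]:
            parents[node] = choice
            perturbed.add(node)

    def find_cycle() -> Optional[List[Pattern]]:
        seen_ok: set = {root}
        for start in sorted(parents):
            trail: Dict[Pattern, int] = {}
            node, path = start, []
            while node not in seen_ok:
                if node in trail:
                    return path[trail[node]:]
                trail[node] = len(path)
                path.append(node)
                node = parents[node]
            seen_ok.update(path)
        return None

    while True:
        cycle = find_cycle()
        if cycle is None:
            break
        fixable = sorted(n for n in cycle if n in perturbed)
        if not fixable:  # cannot happen: the original branching is acyclic
            raise AssertionError("cycle without perturbed nodes")
        node = fixable[0]
        parents[node] = original[node]
        perturbed.discard(node)

    out = ProgressionTree(tree.panel)
    for pat in tree.nodes():
        nd = tree.node(pat)
        out.add_node(pat, nd.observed, nd.frequency)
    for chi in sorted(parents):
        par = parents[chi]
        ev = g.edges[par, chi]["event"]
        out.add_edge(par, chi, (ev,), freqs.prob(ev))
    return out


def _tally_tree(
    tree: ProgressionTree, weighting: str = "clonal"
) -> Dict[Tuple[int, ...], float]:
    """Event-type tallies over a tree's edges.

    ``clonal`` weights each edge by the clonal frequency of the mutation
    it introduces — the total observed cell count of the subtree below
    it, since every descendant cell inherited the event.  ``cells``
    weights by the child node's own cell count; ``edges`` counts each
    edge once.
    """
    tallies: Dict[Tuple[int, ...], float] = {}
    for _, chi, edge in tree.edges():
        if weighting == "clonal":
            w = float(
                sum(tree.node(p).frequency for p in tree.subtree(chi))
            )
        elif weighting == "cells":
            w = float(tree.node(chi).frequency)
        else:
            w = 1.0
        for ev in edge.events:
            tallies[ev] = tallies.get(ev, 0.0) + w
    return tallies


def _initial_frequencies(
    g: nx.DiGraph, panel: ProbePanel, floor: float
) -> MutationFrequencies:
    evs = allowed_event_types(panel.n_genes)
    tallies: Dict[Tuple[int, ...], float] = {}
    for u, v, data in g.edges(data=True):
        tallies[data["event"]] = tallies.get(data["event"], 0.0) + 1.0
    if not tallies:
        return MutationFrequencies.uniform(evs)
    return MutationFrequencies.from_tallies(tallies, evs, floor)


def branching_weight(tree: ProgressionTree, freqs: MutationFrequencies) -> float:
    """Total ``-log p`` of a branching under a frequency estimate."""
    return sum(
        freqs.weight(ev) for _, _, edge in tree.edges() for ev in edge.events
    )


def _prune_steiner_leaves(tree: ProgressionTree) -> ProgressionTree:
    """Drop unobserved leaves (and chains of them): Steiner nodes only
    earn their place by connecting observed states to the root."""
    keep = set(tree.nodes())
    changed = True
    while changed:
        changed = False
        children: Dict[Pattern, int] = {p: 0 for p in keep}
        for chi in keep:
            par = tree.parent(chi)
            if par in children and chi != tree.root:
                children[par] += 1
        for pat in sorted(keep):
            if pat == tree.root:
                continue
            if tree.is_steiner(pat) and children[pat] == 0:
                keep.discard(pat)
                changed = True
    if keep == set(tree.nodes()):
        return tree
    out = ProgressionTree(tree.panel)
    for pat in sorted(keep):
        nd = tree.node(pat)
        out.add_node(pat, nd.observed, nd.frequency)
    for pat in sorted(keep):
        if pat == tree.root:
            continue
        edge = tree.edge(pat)
        out.add_edge(tree.parent(pat), pat, edge.events, edge.probability)
    return out


def fit_single_gene_tree(
    ds: Dataset,
    panel: ProbePanel,
    gene: str,
    config: Optional[EMConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[ProgressionTree, MutationFrequencies]:
    """Infer the ``(ploidy, gene)`` progression tree of one gene probe.

    Returns the lowest-weight branching encountered across EM restarts
    together with the frequency estimate that produced it.  The result is
    deterministic given ``rng``.
    """
    config = config or EMConfig()
    if rng is None:
        rng = np.random.default_rng(0)
    sub = ds.marginalize([panel.ploidy_probe, gene])
    sub_panel = sub.panel
    evs = allowed_event_types(sub_panel.n_genes)

    observed = build_observed_graph(sub)
    if config.init == "uniform":
        init_freqs = MutationFrequencies.uniform(evs)
    else:
        init_freqs = _initial_frequencies(observed, sub_panel, config.floor)
    possible = build_possible_graph(sub_panel)

    def make_graph(freqs):
        g = insert_steiner_nodes(observed, freqs, sub_panel, possible)
        if config.augment_paths:
            g = augment_likely_paths(g, freqs, sub_panel, possible)
        return g

    graph = make_graph(init_freqs)

    best_tree: Optional[ProgressionTree] = None
    best_weight = np.inf
    best_freqs = init_freqs
    for _ in range(max(config.restarts, 1)):
        freqs = init_freqs.copy()
        for _ in range(config.max_iters):
            if config.resteiner:
                graph = make_graph(freqs)
            branching = max_weight_branching(graph, freqs, sub_panel)
            if config.retention == "best":
                w = branching_weight(branching, freqs)
                if w < best_weight - 1e-12:
                    best_weight, best_tree, best_freqs = w, branching, freqs
            perturbed = randomize_branching(branching, graph, freqs, rng, config.eps)
            tallies = _tally_tree(perturbed, weighting=config.tally_weighting)
            if sum(tallies.values()) <= 0:
                tallies = _tally_tree(perturbed, weighting="edges")
            new_freqs = MutationFrequencies.from_tallies(tallies, evs, config.floor)
            delta = new_freqs.max_abs_diff(freqs)
            freqs = new_freqs
            if delta < config.tol:
                break
        # score the converged frequencies' own optimal branching too
        if config.resteiner:
            graph = make_graph(freqs)
        branching = max_weight_branching(graph, freqs, sub_panel)
        w = branching_weight(branching, freqs)
        if config.retention == "best":
            if w < best_weight - 1e-12:
                best_weight, best_tree, best_freqs = w, branching, freqs
        else:
            best_weight, best_tree, best_freqs = w, branching, freqs

    assert best_tree is not None
    best_tree = _prune_steiner_leaves(best_tree)
    # annotate edges with the final frequency estimate
    final = ProgressionTree(best_tree.panel, meta={"gene": gene})
    for pat in best_tree.nodes():
        nd = best_tree.node(pat)
        final.add_node(pat, nd.observed, nd.frequency)
    for par, chi, edge in best_tree.edges():
        ev = edge.events[0]
        final.add_edge(par, chi, (ev,), best_freqs.prob(ev))
    return final, best_freqs
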