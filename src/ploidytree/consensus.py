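"""Consensus graphs across per-sample trees and sharing statistics for
paired samples.

The consensus graph is the union of the nodes and edges of two or more
trees on the same probe panel, annotated with which trees contain each
element.  Sharing statistics quantify how much of the observed cell-state
space two trees have in common: the fraction of observed states present
in both trees, the fraction additionally reachable from the diploid root
in both, and the fraction reachable through a *shared path* (every edge
present in both trees).  Each comes unweighted (state counts) and
weighted (pooled cell proportions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .datamodel import Dataset, Pattern, ProgressionTree
from .errors import ContractError

Edge = Tuple[Pattern, Pattern]


@dataclass
class ConsensusGraph:
    """Union graph with per-tree membership annotations."""

    panel: object
    node_members: Dict[Pattern, FrozenSet[int]]
    node_observed: Dict[Pattern, FrozenSet[int]]
    edge_members: Dict[Edge, FrozenSet[int]]

    @property
    def root(self) -> Pattern:
        return self.panel.root

    def nodes(self) -> Tuple[Pattern, ...]:
        return tuple(sorted(self.node_members))

    def edges(self) -> Tuple[Edge, ...]:
        return tuple(sorted(self.edge_members))

    def shared_nodes(self) -> Tuple[Pattern, ...]:
        k = max(len(m) for m in self.node_members.values())
        return tuple(
            p for p in self.nodes() if len(self.node_members[p]) > 1
        ) if k > 1 else ()


def build_consensus(trees: Sequence[ProgressionTree]) -> ConsensusGraph:
    """Union the nodes and edges of trees on identical panels, recording
    membership sets."""
    if len(trees) < 2:
        raise ContractError("need at least two trees")
    panel = trees[0].panel
    for t in trees[1:]:
        if t.panel != panel:
            raise ContractError("trees are on different probe panels")
    node_members: Dict[Pattern, Set[int]] = {}
    node_observed: Dict[Pattern, Set[int]] = {}
    edge_members: Dict[Edge, Set[int]] = {}
    for k, t in enumerate(trees, start=1):
        for pat in t.nodes():
            node_members.setdefault(pat, set()).add(k)
            if t.node(pat).observed:
                node_observed.setdefault(pat, set()).add(k)
        for par, chi, _ in t.edges():
            edge_members.setdefault((par, chi), set()).add(k)
    return ConsensusGraph(
        panel,
        {p: frozenset(s) for p, s in sorted(node_members.items())},
        {p: frozenset(s) for p, s in sorted(node_observed.items())},
        {e: frozenset(s) for e, s in sorted(edge_members.items())},
    )


def consensus_dot(graph: ConsensusGraph) -> str:
    """DOT rendering of a consensus graph; elements present in every tree
    are drawn bold, others dashed."""
    n_trees = max(
        (max(m, default=0) for m in graph.node_members.values()), default=0
    )
    lines = ["digraph consensus {"]
    for pat in graph.nodes():
        label = ",".join(map(str, pat))
        style = "bold" if len(graph.node_members[pat]) == n_trees else "dashed"
        lines.append(f'  "{label}" [label="{label}", style={style}];')
    for par, chi in graph.edges():
        lp = ",".join(map(str, par))
        lc = ",".join(map(str, chi))
        members = graph.edge_members[(par, chi)]
        style = "bold" if len(members) == n_trees else "dashed"
        lines.append(f'  "{lp}" -> "{lc}" [style={style}];')
    lines.append("}")
    return "\n".join(lines) + "\n"


@dataclass
class SharingStatistics:
    """Six sharing fractions for a pair of trees; each statistic comes as
    an (unweighted, weighted) pair and they are ordered
    shared_path <= shared_reachable <= shared_nodes variant-wise."""

    shared_nodes: Tuple[float, float]
    shared_reachable: Tuple[float, float]
    shared_path: Tuple[float, float]

    def as_rows(self) -> List[Tuple[str, str, float]]:
        return [
            ("shared_nodes", "unweighted", self.shared_nodes[0]),
            ("shared_nodes", "weighted", self.shared_nodes[1]),
            ("shared_reachable", "unweighted", self.shared_reachable[0]),
            ("shared_reachable", "weighted", self.shared_reachable[1]),
            ("shared_path", "unweighted", self.shared_path[0]),
            ("shared_path", "weighted", self.shared_path[1]),
        ]


def _reachable(tree: ProgressionTree) -> Set[Pattern]:
    return set(tree.subtree(tree.root))


def _shared_path_reachable(
    ta: ProgressionTree, tb: ProgressionTree
) -> Set[Pattern]:
    """States reachable from the root through edges present in both trees."""
    shared_edges = {(p, c) for p, c, _ in ta.edges()} & {
        (p, c) for p, c, _ in tb.edges()
    }
    adj: Dict[Pattern, List[Pattern]] = {}
    for p, c in shared_edges:
        adj.setdefault(p, []).append(c)
    seen = {ta.root}
    stack = [ta.root]
    while stack:
        u = stack.pop()
        for v in adj.get(u, ()):
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return seen


def sharing_statistics(
    ta: ProgressionTree,
    tb: ProgressionTree,
    ds_a: Dataset,
    ds_b: Dataset,
) -> SharingStatistics:
    """Sharing fractions between the trees of two paired samples.

    The universe is the set of distinct observed patterns in the union
    of the two samples; Steiner-only states never count.  Weighted
    variants use pooled cell proportions
    ``(cells_A + cells_B) / (total_A + total_B)``.  All statistics are
    symmetric in the two samples.
    """
    if ta.panel != tb.panel:
        raise ContractError("trees are on different probe panels")
    universe = sorted(set(ds_a.counts) | set(ds_b.counts))
    total = ds_a.total_cells + ds_b.total_cells

    def mass(pat: Pattern) -> float:
        return (ds_a.frequency(pat) + ds_b.frequency(pat)) / total

    in_both = [p for p in universe if p in ta and p in tb]
    reach = _reachable(ta) & _reachable(tb)
    reachable_both = [p for p in in_both if p in reach]
    path_reach = _shared_path_reachable(ta, tb)
    path_both = [p for p in reachable_both if p in path_reach]

    denom_n = len(universe)
    denom_w = sum(mass(p) for p in universe)  # = 1, kept explicit

    def frac(patterns: List[Pattern]) -> Tuple[float, float]:
        return (
            len(patterns) / denom_n,
            sum(mass(p) for p in patterns) / denom_w,
        )

    return SharingStatistics(
        shared_nodes=frac(in_both),
        shared_reachable=frac(reachable_both),
        shared_path=frac(path_both),
    )
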