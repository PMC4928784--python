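"""Validation and tree-complexity statistics.

* ``w_statistic`` — chi-square-style discrepancy between inferred and
  true event-type frequencies, W = sum_i (P_i - A_i)^2 / A_i.
* ``reconstruction_error`` — bipartition distance between a true and an
  inferred tree: delete each edge, match identical splits of the shared
  node set between the two trees by maximum matching, and score
  R = (1 - M / (|P_s| + |P_g| - M)) x 100 (0 best, 100 worst).
* tree weight (sum of -log edge probabilities), average edge weight
  (per-edge entropy), expected observed-node depth, Shannon entropy and
  Simpson index of the event distribution, coverage of observed states,
  Steiner-node fraction, and a bootstrap estimate of how many distinct
  cell states a resampled sample of the same size would retain.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Dict, FrozenSet, Mapping, Optional, Tuple, Union

import numpy as np

from .datamodel import Dataset, Pattern, ProgressionTree
from .errors import ContractError
from .events import MutationFrequencies, allowed_event_types

Dist = Union[MutationFrequencies, Mapping[Tuple[int, ...], float]]


def _as_mapping(dist: Dist) -> Mapping[Tuple[int, ...], float]:
    return dist.probs if isinstance(dist, MutationFrequencies) else dist


def w_statistic(predicted: Dist, actual: Dist) -> float:
    """W = sum_i (P_i - A_i)^2 / A_i over the event-type support.

    Every type appearing in either distribution must have A_i > 0.
    """
    p = _as_mapping(predicted)
    a = _as_mapping(actual)
    support = set(p) | set(a)
    w = 0.0
    for ev in support:
        ai = a.get(ev, 0.0)
        pi = p.get(ev, 0.0)
        if ai <= 0:
            raise ContractError(f"actual frequency of {ev} is zero")
        w += (pi - ai) ** 2 / ai
    return w


def _bipartitions(tree: ProgressionTree) -> Tuple[FrozenSet[Pattern], ...]:
    """For each edge, the node set of the subtree below it."""
    return tuple(
        frozenset(tree.subtree(chi)) for _, chi, _ in tree.edges()
    )


def split_similarity(
    part_s: FrozenSet[Pattern],
    part_g: FrozenSet[Pattern],
    shared: FrozenSet[Pattern],
) -> float:
    """Agreement of two edge-deletion splits on the shared node set.

    ``shared`` must exclude the root (which no split ever cuts off).
    The score is the fraction of shared states that both splits place on
    the same side, i.e. one minus the normalized symmetric difference of
    the cut-off sets; splits that cut off no shared state at all carry
    no evidence and score 0.
    """
    s = part_s & shared
    g = part_g & shared
    if not (s | g) or not shared:
        return 0.0
    agree = len(s & g) + len(shared) - len(s | g)
    return agree / len(shared)


def reconstruction_error(
    simulated: ProgressionTree, generated: ProgressionTree
) -> float:
    """Percent bipartition mismatch between a true and an inferred tree.

    Deleting each edge splits a tree's node set in two; the subtree-side
    sets of the two trees are matched one-to-one by a maximum-weight
    bipartite matching whose weights are the agreement of the splits
    restricted to the shared (pattern-labeled) non-root node set.  With
    M the total matched weight, R = (1 - M / (|P_s| + |P_g| - M)) x 100,
    ranging from 0 (identical trees) to 100 (no split in common).
    """
    from scipy.optimize import linear_sum_assignment

    shared = (
        frozenset(simulated.nodes()) & frozenset(generated.nodes())
    ) - {simulated.root}
    parts_s = _bipartitions(simulated)
    parts_g = _bipartitions(generated)
    if not parts_s and not parts_g:
        return 0.0
    if not parts_s or not parts_g:
        return 100.0
    sim = np.array(
        [
            [split_similarity(ps, pg, shared) for pg in parts_g]
            for ps in parts_s
        ]
    )
    rows, cols = linear_sum_assignment(sim, maximize=True)
    matched = float(sim[rows, cols].sum())
    denom = len(parts_s) + len(parts_g) - matched
    if denom <= 0:
        return 0.0
    return (1.0 - matched / denom) * 100.0


def tree_weight(tree: ProgressionTree) -> float:
    """Sum of ``-log p`` over the tree's edges."""
    total = 0.0
    for _, chi, edge in tree.edges():
        if not edge.probability > 0:
            raise ContractError(f"edge into {chi} has probability <= 0")
        total += -math.log(edge.probability)
    return total


def avg_edge_weight(tree: ProgressionTree) -> float:
    """Mean ``-log p`` per edge; equals the Shannon entropy of the
    tree's own event distribution when edges are weighted by it."""
    if tree.n_edges == 0:
        raise ContractError("tree has no edges")
    return tree_weight(tree) / tree.n_edges


def tree_event_distribution(
    tree: ProgressionTree, floor: float = 0.0
) -> MutationFrequencies:
    """Empirical distribution of the decomposed edge event types of a
    tree ('the parameters inferred from the tree')."""
    evs = allowed_event_types(tree.panel.n_genes)
    tallies: Dict[Tuple[int, ...], float] = {}
    for _, _, edge in tree.edges():
        for ev in edge.events:
            tallies[ev] = tallies.get(ev, 0.0) + 1.0
    return MutationFrequencies.from_tallies(tallies, evs, floor)


def reweight_edges(
    tree: ProgressionTree, freqs: MutationFrequencies
) -> ProgressionTree:
    """Copy of ``tree`` with each edge's probability replaced by the
    product of its component event probabilities under ``freqs``."""
    out = ProgressionTree(tree.panel, meta=tree.meta)
    for pat in tree.nodes():
        nd = tree.node(pat)
        out.add_node(pat, nd.observed, nd.frequency)
    for par, chi, edge in tree.edges():
        prob = 1.0
        for ev in edge.events:
            prob *= freqs.prob(ev)
        out.add_edge(par, chi, edge.events, prob)
    return out


def expected_depth(tree: ProgressionTree, ds: Dataset) -> float:
    """Cell-weighted mean depth of the observed states; the diploid root
    has depth zero."""
    depths = tree.depths()
    total = ds.total_cells
    acc = 0.0
    for pat, cnt in ds.counts.items():
        if pat not in depths:
            raise ContractError(f"observed pattern {pat} missing from tree")
        acc += depths[pat] * cnt
    return acc / total


def shannon_entropy(freqs: Dist) -> float:
    """SE = -sum p ln p (0 ln 0 := 0)."""
    return float(
        -sum(p * math.log(p) for p in _as_mapping(freqs).values() if p > 0)
    )


def simpson_index(freqs: Dist) -> float:
    """SI = sum p^2."""
    return float(sum(p * p for p in _as_mapping(freqs).values()))


def coverage(tree: ProgressionTree, ds: Dataset) -> float:
    """Fraction of the sample's distinct observed states present in the
    tree."""
    pats = ds.patterns
    return sum(1 for p in pats if p in tree) / len(pats)


def steiner_fraction(tree: ProgressionTree) -> float:
    """Fraction of tree nodes that are unobserved (Steiner) states."""
    return len(tree.steiner_patterns()) / tree.n_nodes


def state_retention_bootstrap(
    ds: Dataset, n_reps: int = 100, rng: Optional[np.random.Generator] = None
) -> float:
    """Bootstrap estimate of observed-state retention.

    Each replicate resamples ``total_cells`` cells with replacement from
    the empirical pattern distribution; the statistic is the mean
    fraction of the originally observed distinct patterns that reappear.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    pats = ds.patterns
    counts = np.array([ds.counts[p] for p in pats], dtype=float)
    probs = counts / counts.sum()
    n = ds.total_cells
    fractions = np.empty(n_reps)
    for r in range(n_reps):
        draw = rng.multinomial(n, probs)
        fractions[r] = np.count_nonzero(draw) / len(pats)
    return float(fractions.mean())
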