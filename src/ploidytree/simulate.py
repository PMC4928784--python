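"""Random progression trees and single-cell samples under the
copy-number event model, plus the end-to-end simulation study.

A tree is grown from the diploid root by repeatedly picking an existing
node uniformly at random, drawing an event type from the configured rate
distribution, and attaching the resulting state if it is in bounds and
not already in the tree, until the requested number of distinct states
exists.  Cells are then assigned to nodes multinomially with
symmetric-Dirichlet node proportions.

``RATE_SETS`` holds three benchmark event-rate distributions (one ploidy
probe + two gene probes) used throughout validation; each is the realized
edge-type distribution of a published simulation design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .datamodel import Dataset, Pattern, ProbePanel, ProgressionTree
from .errors import ContractError
from .events import MutationFrequencies, allowed_event_types

#: benchmark rate sets over the 8 event types for 2 gene probes
_RAW_RATE_SETS: Dict[str, Dict[Tuple[int, int, int], float]] = {
    "dataset1": {
        (-1, -1, -1): 0.0147,
        (-1, 0, 0): 0.00139,
        (0, -1, 0): 0.298,
        (0, 0, -1): 0.0355,
        (0, 0, 1): 0.379,
        (0, 1, 0): 0.0294,
        (1, 0, 0): 0.0161,
        (1, 1, 1): 0.226,
    },
    "dataset2": {
        (-1, -1, -1): 0.0177,
        (-1, 0, 0): 0.00168,
        (0, -1, 0): 0.203,
        (0, 0, -1): 0.0502,
        (0, 0, 1): 0.483,
        (0, 1, 0): 0.0228,
        (1, 0, 0): 0.0286,
        (1, 1, 1): 0.193,
    },
    "dataset3": {
        (-1, -1, -1): 0.0123,
        (-1, 0, 0): 0.000929,
        (0, -1, 0): 0.196,
        (0, 0, -1): 0.187,
        (0, 0, 1): 0.211,
        (0, 1, 0): 0.224,
        (1, 0, 0): 0.0213,
        (1, 1, 1): 0.147,
    },
}


def rate_set(name: str) -> MutationFrequencies:
    """A benchmark rate distribution, renormalized to sum exactly to 1."""
    try:
        raw = _RAW_RATE_SETS[name]
    except KeyError:
        raise ContractError(
            f"unknown rate set {name!r}; choose from {sorted(_RAW_RATE_SETS)}"
        ) from None
    total = sum(raw.values())
    return MutationFrequencies({ev: p / total for ev, p in raw.items()})


RATE_SET_NAMES = tuple(sorted(_RAW_RATE_SETS))


@dataclass
class SimulationConfig:
    """Study conditions for the simulator.

    Defaults follow the validation design: two gene probes plus one
    ploidy probe, 100 random trees of about 38 distinct states each, and
    250 cells per sample.
    """

    rates: MutationFrequencies
    n_trees: int = 100
    nodes_per_tree: int = 38
    cells_per_sample: int = 250
    seed: int = 0
    max_copy: int = 9

    def __post_init__(self) -> None:
        n_probes = len(next(iter(self.rates.probs)))
        expected = set(allowed_event_types(n_probes - 1))
        if set(self.rates.probs) != expected:
            raise ContractError(
                "rates must cover exactly the allowed event types"
            )
        if min(self.n_trees, self.nodes_per_tree, self.cells_per_sample) < 1:
            raise ContractError("n_trees, nodes_per_tree, cells_per_sample >= 1")

    @property
    def n_genes(self) -> int:
        return len(next(iter(self.rates.probs))) - 1

    @property
    def panel(self) -> ProbePanel:
        genes = tuple(f"g{i + 1}" for i in range(self.n_genes))
        return ProbePanel("ploidy", genes, self.max_copy)


@dataclass
class SimulatedInstance:
    true_tree: ProgressionTree
    dataset: Dataset
    realized_rates: MutationFrequencies


def simulate_tree(cfg: SimulationConfig, rng: np.random.Generator) -> ProgressionTree:
    """Grow one random progression tree from the diploid root."""
    panel = cfg.panel
    events = sorted(cfg.rates.probs)
    probs = np.array([cfg.rates.probs[ev] for ev in events])
    probs = probs / probs.sum()
    tree = ProgressionTree(panel)
    nodes: List[Pattern] = [panel.root]
    have = {panel.root}
    cap = panel.max_copy
    max_attempts = 10000 * cfg.nodes_per_tree
    attempts = 0
    while len(nodes) < cfg.nodes_per_tree:
        attempts += 1
        if attempts > max_attempts:
            raise ContractError(
                "could not grow the requested number of distinct states"
            )
        parent = nodes[rng.integers(len(nodes))]
        ev = events[rng.choice(len(events), p=probs)]
        child = tuple(s + d for s, d in zip(parent, ev))
        if child in have:
            continue
        if not (1 <= child[0] <= cap) or any(
            not 0 <= g <= cap for g in child[1:]
        ):
            continue
        tree.add_node(child)
        tree.add_edge(parent, child, (ev,), cfg.rates.prob(ev))
        nodes.append(child)
        have.add(child)
    return tree


def realized_rates(tree: ProgressionTree) -> MutationFrequencies:
    """Normalized edge-type tally of a simulated tree."""
    evs = allowed_event_types(tree.panel.n_genes)
    tallies: Dict[Tuple[int, ...], float] = {}
    for _, _, edge in tree.edges():
        for ev in edge.events:
            tallies[ev] = tallies.get(ev, 0.0) + 1.0
    return MutationFrequencies.from_tallies(tallies, evs, floor=0.0)


def simulate_dataset(
    tree: ProgressionTree, cells_per_sample: int, rng: np.random.Generator
) -> Dataset:
    """Draw a single-cell sample: node proportions from a symmetric
    Dirichlet(1), then a multinomial split of the cells."""
    nodes = list(tree.nodes())
    props = rng.dirichlet(np.ones(len(nodes)))
    counts = rng.multinomial(cells_per_sample, props)
    mapping = {
        pat: int(cnt) for pat, cnt in zip(nodes, counts) if cnt > 0
    }
    ds = Dataset(tree.panel, mapping, sample_id="simulated")
    # annotate the true tree's nodes with the drawn frequencies
    for pat in nodes:
        node = tree.node(pat)
        node.observed = pat in mapping
        node.frequency = mapping.get(pat, 0)
    return ds


def simulate_instance(
    cfg: SimulationConfig, rng: np.random.Generator
) -> SimulatedInstance:
    tree = simulate_tree(cfg, rng)
    ds = simulate_dataset(tree, cfg.cells_per_sample, rng)
    return SimulatedInstance(tree, ds, realized_rates(tree))


@dataclass
class StudyResult:
    """Pooled and per-instance results of a simulation study."""

    config: SimulationConfig
    predicted: Dict[Tuple[int, ...], float]  # pooled inferred event dist.
    actual: Dict[Tuple[int, ...], float]     # pooled realized event dist.
    w: float
    records: List[Dict[str, float]]

    def mean(self, key: str) -> float:
        return float(np.mean([r[key] for r in self.records]))


def run_simulation_study(
    cfg: SimulationConfig,
    em_config=None,
    merge_config=None,
) -> StudyResult:
    """Simulate ``cfg.n_trees`` instances, run the full inference
    pipeline on each, and pool the validation statistics.

    Per instance: two single-gene trees are fit by EM, merged by the
    MILP, and compared to the true tree.  Predicted rates pool the
    decomposed edge-event tallies of all inferred trees; actual rates
    pool the edge tallies of all simulated trees.  The W statistic is
    computed over event types with nonzero pooled actual tally.
    """
    from .evaluate import (
        avg_edge_weight,
        coverage,
        reconstruction_error,
        reweight_edges,
        steiner_fraction,
        tree_event_distribution,
        tree_weight,
        w_statistic,
    )
    from .pipeline import RunConfig, run_sample_analysis

    run_cfg = RunConfig(seed=cfg.seed)
    if em_config is not None:
        run_cfg.em = em_config
    if merge_config is not None:
        run_cfg.merge = merge_config

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_trees)
    evs = allowed_event_types(cfg.n_genes)
    pred_tally = {ev: 0.0 for ev in evs}
    act_tally = {ev: 0.0 for ev in evs}
    records: List[Dict[str, float]] = []
    for k in range(cfg.n_trees):
        rng = np.random.default_rng(seeds[k])
        inst = simulate_instance(cfg, rng)
        result = run_sample_analysis(inst.dataset, run_cfg, rng=rng)
        merged = result.merged_tree

        for _, _, edge in inst.true_tree.edges():
            for ev in edge.events:
                act_tally[ev] += 1.0
        for _, _, edge in merged.edges():
            for ev in edge.events:
                pred_tally[ev] += 1.0

        dist = tree_event_distribution(merged)
        weighted = reweight_edges(merged, dist)
        records.append(
            {
                "r": reconstruction_error(inst.true_tree, merged),
                "tree_weight": tree_weight(weighted),
                "avg_edge_weight": avg_edge_weight(weighted)
                if weighted.n_edges
                else 0.0,
                "steiner_fraction": steiner_fraction(merged),
                "coverage": coverage(merged, inst.dataset),
                "n_nodes": merged.n_nodes,
                "n_edges": merged.n_edges,
            }
        )

    pred_total = sum(pred_tally.values())
    act_total = sum(act_tally.values())
    predicted = {ev: t / pred_total for ev, t in pred_tally.items()}
    actual = {ev: t / act_total for ev, t in act_tally.items()}
    support = [ev for ev in evs if actual[ev] > 0]
    w = w_statistic(
        {ev: predicted[ev] for ev in support},
        {ev: actual[ev] for ev in support},
    )
    return StudyResult(cfg, predicted, actual, w, records)
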