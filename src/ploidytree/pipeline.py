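"""End-to-end orchestration: single-gene fits, tree merging, and paired
consensus analysis under one reproducible configuration."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .consensus import ConsensusGraph, SharingStatistics, build_consensus, sharing_statistics
from .datamodel import Dataset, ProgressionTree
from .errors import ContractError
from .events import MutationFrequencies
from .merge import MergeConfig, merge_all
from .single_gene import EMConfig, fit_single_gene_tree

logger = logging.getLogger("ploidytree")


@dataclass
class RunConfig:
    """One global seed plus the EM and MILP settings; the seed determines
    every source of randomness in a run."""

    seed: int = 0
    em: EMConfig = field(default_factory=EMConfig)
    merge: MergeConfig = field(default_factory=MergeConfig)


@dataclass
class SampleResult:
    dataset: Dataset
    single_trees: Dict[str, ProgressionTree]
    single_freqs: Dict[str, MutationFrequencies]
    merged_tree: ProgressionTree


@dataclass
class PairedResult:
    sample_a: SampleResult
    sample_b: SampleResult
    consensus: ConsensusGraph
    statistics: SharingStatistics


def run_sample_analysis(
    ds: Dataset,
    cfg: Optional[RunConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> SampleResult:
    """Fit one single-gene tree per gene probe, then merge them all.

    Deterministic given the configuration seed (or a caller-supplied
    generator).
    """
    cfg = cfg or RunConfig()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    panel = ds.panel
    trees: Dict[str, ProgressionTree] = {}
    freqs: Dict[str, MutationFrequencies] = {}
    for gene in panel.gene_probes:
        tree, f = fit_single_gene_tree(ds, panel, gene, cfg.em, rng)
        trees[gene] = tree
        freqs[gene] = f
        logger.debug("single-gene tree for %s: %d nodes", gene, tree.n_nodes)
    if panel.n_genes == 1:
        merged = trees[panel.gene_probes[0]]
    else:
        merged = merge_all(
            [trees[g] for g in panel.gene_probes], ds, cfg.merge
        )
    return SampleResult(ds, trees, freqs, merged)


def run_paired_analysis(
    ds_a: Dataset,
    ds_b: Dataset,
    cfg: Optional[RunConfig] = None,
) -> PairedResult:
    """Per-sample analysis of a paired case followed by consensus graph
    construction and sharing statistics."""
    if ds_a.panel != ds_b.panel:
        raise ContractError("paired samples must share a probe panel")
    cfg = cfg or RunConfig()
    seq = np.random.SeedSequence(cfg.seed)
    rng_a, rng_b = (np.random.default_rng(s) for s in seq.spawn(2))
    res_a = run_sample_analysis(ds_a, cfg, rng=rng_a)
    res_b = run_sample_analysis(ds_b, cfg, rng=rng_b)
    graph = build_consensus([res_a.merged_tree, res_b.merged_tree])
    stats = sharing_statistics(
        res_a.merged_tree, res_b.merged_tree, ds_a, ds_b
    )
    return PairedResult(res_a, res_b, graph, stats)
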