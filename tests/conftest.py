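"""Shared fixtures: probe panels, small datasets, and random trees."""

import numpy as np
import pytest

from ploidytree import Dataset, ProbePanel


@pytest.fixture
def single_panel():
    """One ploidy probe plus one gene probe (single-gene analyses)."""
    return ProbePanel("ploidy", ("g",))


@pytest.fixture
def two_gene_panel():
    return ProbePanel("ploidy", ("g1", "g2"))


@pytest.fixture
def cc_panel():
    """Panel mirroring the cervical-cancer study probes."""
    return ProbePanel("cep", ("LAMP3", "PROX1", "PRKAA1", "CCND1"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(single_panel):
    return Dataset(single_panel, {(2, 2): 50, (2, 3): 50})


def make_random_dataset(panel, rng, n_patterns=8, cells=120):
    """Random dataset helper used by property tests."""
    from ploidytree.events import allowed_transitions

    states = {panel.root}
    frontier = [panel.root]
    while len(states) < n_patterns:
        base = frontier[rng.integers(len(frontier))]
        succs = allowed_transitions(base, panel)
        nxt = succs[rng.integers(len(succs))][0]
        if nxt not in states:
            states.add(nxt)
            frontier.append(nxt)
    states = sorted(states)
    weights = rng.dirichlet(np.ones(len(states)))
    counts = rng.multinomial(cells, weights)
    mapping = {s: int(c) for s, c in zip(states, counts) if c > 0}
    if not mapping:
        mapping = {panel.root: cells}
    return Dataset(panel, mapping)
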