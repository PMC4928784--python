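"""Core data types: probe panels, cell-count datasets, progression trees.

A *cell count pattern* is an immutable integer tuple ``(p, g1, ..., gn)``
holding the copy number of the ploidy probe followed by those of the gene
probes.  A dataset maps distinct patterns to the number of cells in which
each was observed.  A progression tree is a rooted directed tree over
patterns whose root is the all-2 (diploid wild-type) pattern; unobserved
intermediate states inserted during inference are flagged as Steiner
nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

from . import events
from .errors import ContractError, InputError, InvariantError

Pattern = Tuple[int, ...]


@dataclass(frozen=True)
class ProbePanel:
    """The probes measured in a study: one ploidy probe (always first)
    and an ordered list of gene probes, with a shared copy-number cap."""

    ploidy_probe: str
    gene_probes: Tuple[str, ...]
    max_copy: int = 9

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_probes", tuple(self.gene_probes))
        names = self.probe_names
        if len(set(names)) != len(names) or any(not n for n in names):
            raise ContractError("probe names must be unique and non-empty")
        if self.max_copy < 2:
            raise ContractError("max_copy must be >= 2")
        if not self.gene_probes:
            raise ContractError("panel needs at least one gene probe")

    @property
    def probe_names(self) -> Tuple[str, ...]:
        return (self.ploidy_probe,) + self.gene_probes

    @property
    def n_genes(self) -> int:
        return len(self.gene_probes)

    @property
    def n_probes(self) -> int:
        return self.n_genes + 1

    @property
    def root(self) -> Pattern:
        """The diploid wild-type pattern: two copies of every probe."""
        return (2,) * self.n_probes

    def index_of(self, probe: str) -> int:
        try:
            return self.probe_names.index(probe)
        except ValueError:
            raise ContractError(f"unknown probe {probe!r}") from None

    def subset(self, probes: Sequence[str]) -> "ProbePanel":
        """Panel restricted to ``probes`` (must include the ploidy probe);
        gene order follows this panel, not the argument order."""
        keep = set(probes)
        unknown = keep - set(self.probe_names)
        if unknown:
            raise ContractError(f"unknown probes {sorted(unknown)}")
        if self.ploidy_probe not in keep:
            raise ContractError("subset must contain the ploidy probe")
        genes = tuple(g for g in self.gene_probes if g in keep)
        if not genes:
            raise ContractError("subset must keep at least one gene probe")
        return ProbePanel(self.ploidy_probe, genes, self.max_copy)

    def validate_pattern(
        self, pattern: Sequence[int], allow_zero_ploidy: bool = False
    ) -> Pattern:
        pat = tuple(int(x) for x in pattern)
        if len(pat) != self.n_probes:
            raise ContractError(
                f"pattern {pat} has {len(pat)} entries, panel has "
                f"{self.n_probes} probes"
            )
        lo_p = 0 if allow_zero_ploidy else 1
        if not lo_p <= pat[0] <= self.max_copy:
            raise InputError(f"ploidy count {pat[0]} outside [{lo_p}, {self.max_copy}]")
        for g in pat[1:]:
            if not 0 <= g <= self.max_copy:
                raise InputError(f"gene count {g} outside [0, {self.max_copy}]")
        return pat


@dataclass
class Dataset:
    """Mapping of cell count patterns to positive cell counts for one
    tumor sample."""

    panel: ProbePanel
    counts: Dict[Pattern, int]
    sample_id: str = ""
    patient_id: str = ""
    stage_label: str = ""

    def __post_init__(self) -> None:
        if not self.counts:
            raise InputError("dataset contains no cells")
        clean: Dict[Pattern, int] = {}
        for pat, cnt in self.counts.items():
            pat = self.panel.validate_pattern(pat)
            cnt = int(cnt)
            if cnt < 1:
                raise ContractError(f"count for {pat} must be >= 1, got {cnt}")
            if pat in clean:
                raise ContractError(f"duplicate pattern {pat}")
            clean[pat] = cnt
        self.counts = clean

    @property
    def total_cells(self) -> int:
        return sum(self.counts.values())

    @property
    def patterns(self) -> Tuple[Pattern, ...]:
        return tuple(sorted(self.counts))

    def frequency(self, pattern: Pattern) -> int:
        return self.counts.get(tuple(pattern), 0)

    def marginalize(self, probes: Sequence[str]) -> "Dataset":
        """Restrict to a probe subset (must include the ploidy probe),
        summing the counts of patterns that agree on the kept dimensions.

        Total cell count is conserved.
        """
        sub = self.panel.subset(probes)
        idx = [self.panel.index_of(name) for name in sub.probe_names]
        out: Dict[Pattern, int] = {}
        for pat, cnt in self.counts.items():
            reduced = tuple(pat[i] for i in idx)
            out[reduced] = out.get(reduced, 0) + cnt
        return Dataset(
            sub, out,
            sample_id=self.sample_id,
            patient_id=self.patient_id,
            stage_label=self.stage_label,
        )


def marginalize(ds: Dataset, probes: Sequence[str]) -> Dataset:
    """Module-level alias for :meth:`Dataset.marginalize`."""
    return ds.marginalize(probes)


@dataclass
class TreeNode:
    observed: bool = False
    frequency: int = 0


@dataclass(frozen=True)
class TreeEdge:
    """An edge of a progression tree.

    ``events`` is the decomposition of the parent-to-child copy-number
    change into allowed event types (a single event for single-gene
    trees; possibly several for merged multi-probe trees).
    ``probability`` is the product of the component event probabilities.
    """

    events: Tuple[Tuple[int, ...], ...]
    probability: float


class ProgressionTree:
    """Rooted directed tree over cell count patterns.

    The root is always the all-2 wild-type pattern; every other node has
    exactly one parent and is reachable from the root.  Nodes carry an
    observed/Steiner flag and the observed cell count; edges carry their
    event decomposition and probability.
    """

    def __init__(self, panel: ProbePanel, meta: Optional[dict] = None):
        self.panel = panel
        self.meta: dict = dict(meta or {})
        root = panel.root
        self._nodes: Dict[Pattern, TreeNode] = {root: TreeNode()}
        self._parent: Dict[Pattern, Pattern] = {}
        self._edges: Dict[Pattern, TreeEdge] = {}  # keyed by child
        self._children: Dict[Pattern, List[Pattern]] = {root: []}

    # -- construction --------------------------------------------------
    @property
    def root(self) -> Pattern:
        return self.panel.root

    def add_node(
        self, pattern: Sequence[int], observed: bool = False, frequency: int = 0
    ) -> Pattern:
        pat = self.panel.validate_pattern(pattern)
        observed, frequency = bool(observed), int(frequency)
        node = self._nodes.get(pat)
        if node is None:
            self._nodes[pat] = TreeNode(observed, frequency)
            self._children[pat] = []
        else:
            node.observed = node.observed or observed
            node.frequency = max(node.frequency, frequency)
        return pat

    def add_edge(
        self,
        parent: Sequence[int],
        child: Sequence[int],
        evs: Optional[Sequence[Sequence[int]]] = None,
        probability: float = 1.0,
    ) -> None:
        par = tuple(int(x) for x in parent)
        chi = tuple(int(x) for x in child)
        if par not in self._nodes or chi not in self._nodes:
            raise ContractError("edge endpoints must be added as nodes first")
        if chi == self.root:
            raise ContractError("the root cannot have a parent")
        if chi in self._parent:
            raise ContractError(f"node {chi} already has a parent")
        if evs is None:
            evs = events.decompose_edge(par, chi)
        self._parent[chi] = par
        self._edges[chi] = TreeEdge(
            tuple(tuple(int(x) for x in e) for e in evs), float(probability)
        )
        self._children[par].append(chi)

    # -- queries --------------------------------------------------------
    def __contains__(self, pattern) -> bool:
        return tuple(pattern) in self._nodes

    def nodes(self) -> Tuple[Pattern, ...]:
        return tuple(sorted(self._nodes))

    def node(self, pattern: Sequence[int]) -> TreeNode:
        return self._nodes[tuple(pattern)]

    def is_steiner(self, pattern: Sequence[int]) -> bool:
        return not self._nodes[tuple(pattern)].observed

    def observed_patterns(self) -> Tuple[Pattern, ...]:
        return tuple(p for p in self.nodes() if self._nodes[p].observed)

    def steiner_patterns(self) -> Tuple[Pattern, ...]:
        return tuple(p for p in self.nodes() if not self._nodes[p].observed)

    def parent(self, child: Sequence[int]) -> Optional[Pattern]:
        return self._parent.get(tuple(child))

    def children(self, parent: Sequence[int]) -> Tuple[Pattern, ...]:
        return tuple(sorted(self._children.get(tuple(parent), ())))

    def edge(self, child: Sequence[int]) -> TreeEdge:
        return self._edges[tuple(child)]

    def edges(self) -> Tuple[Tuple[Pattern, Pattern, TreeEdge], ...]:
        return tuple(
            (self._parent[c], c, self._edges[c]) for c in sorted(self._parent)
        )

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def depths(self) -> Dict[Pattern, int]:
        """Edge-count depth of every node; the root has depth zero."""
        out = {self.root: 0}
        stack = [self.root]
        while stack:
            u = stack.pop()
            for v in self._children.get(u, ()):
                out[v] = out[u] + 1
                stack.append(v)
        return out

    def depth(self, pattern: Sequence[int]) -> int:
        return self.depths()[tuple(pattern)]

    def subtree(self, pattern: Sequence[int]) -> Tuple[Pattern, ...]:
        """All nodes at or below ``pattern``."""
        start = tuple(pattern)
        out = [start]
        stack = [start]
        while stack:
            u = stack.pop()
            for v in self._children.get(u, ()):
                out.append(v)
                stack.append(v)
        return tuple(sorted(out))

    # -- validation ------------------------------------------------------
    def validate(self, strict_events: bool = True) -> None:
        """Check all tree invariants; raise :class:`InvariantError`.

        With ``strict_events`` every edge must be a single allowed event
        (single-gene trees).  Otherwise edges need only decompose into
        allowed events with a ploidy change of at most one (merged
        trees).
        """
        if self.root not in self._nodes:
            raise InvariantError("root missing")
        depths = self.depths()
        if set(depths) != set(self._nodes):
            missing = set(self._nodes) - set(depths)
            raise InvariantError(f"nodes unreachable from root: {sorted(missing)}")
        for pat in self._nodes:
            if pat != self.root and pat not in self._parent:
                raise InvariantError(f"non-root node {pat} has no parent")
            self.panel.validate_pattern(pat)
        for par, chi, edge in self.edges():
            delta = tuple(c - p for p, c in zip(par, chi))
            total = tuple(sum(e[i] for e in edge.events) for i in range(len(delta)))
            if total != delta:
                raise InvariantError(
                    f"edge {par}->{chi}: events sum to {total}, delta is {delta}"
                )
            for ev in edge.events:
                if not events.is_allowed_event(ev):
                    raise InvariantError(f"edge {par}->{chi}: event {ev} not allowed")
            if strict_events and len(edge.events) != 1:
                raise InvariantError(
                    f"edge {par}->{chi} is not a single allowed event"
                )
            if abs(delta[0]) >= 2:
                raise InvariantError(f"edge {par}->{chi} jumps ploidy by {delta[0]}")
            if not (edge.probability > 0 or math.isnan(edge.probability)):
                raise InvariantError(f"edge {par}->{chi} has probability <= 0")

    # -- misc -------------------------------------------------------------
    def copy(self) -> "ProgressionTree":
        t = ProgressionTree(self.panel, meta=self.meta)
        for pat, node in self._nodes.items():
            t.add_node(pat, node.observed, node.frequency)
        for chi, par in self._parent.items():
            e = self._edges[chi]
            t.add_edge(par, chi, e.events, e.probability)
        return t

    def structure(self):
        """Hashable snapshot of topology + annotations (for equality)."""
        return (
            self.panel,
            tuple((p, n.observed, n.frequency) for p, n in sorted(self._nodes.items())),
            tuple(
                (self._parent[c], c, self._edges[c].events,
                 round(self._edges[c].probability, 12))
                for c in sorted(self._parent)
            ),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, ProgressionTree):
            return NotImplemented
        return self.structure() == other.structure()

    def __repr__(self) -> str:
        return (
            f"ProgressionTree(n_nodes={self.n_nodes}, n_edges={self.n_edges}, "
            f"panel={self.panel.probe_names})"
        )
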