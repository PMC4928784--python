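"""Merging progression trees over disjoint gene-probe sets via mixed
integer linear programming.

Given a tree A over ``(ploidy, genes_A)`` with m nodes and a tree B over
``(ploidy, genes_B)`` with n nodes (roots indexed 1), the merged tree
lives on index pairs ``(i, j)``.  Binary variables per pair:

* ``a_ij`` — edge into ``(i, j)`` derived from tree A, i.e. from
  ``(parent_A(i), j)``;
* ``b_ij`` — edge derived from tree B, from ``(i, parent_B(j))``;
* ``c_ij`` — edge derived from both, from ``(parent_A(i), parent_B(j))``;

plus a continuous frequency ``q_ij`` in [0, 1].  A pair is a node of the
merged tree iff ``a_ij + b_ij + c_ij = 1``; the root pair carries the
conventional ``c_11 = 1``.  Constraints force each selected pair's parent
pair to be selected, each node of A and B to be used by at least one
selected edge, and the row/column sums of q to match the observed joint
frequencies p.  The objective minimizes total tree weight (-log edge
probabilities), penalizes pairing nodes of unequal ploidy (rho), penalizes
|p - q| frequency mismatch (sigma), and penalizes dropping observed pairs
(tau).  Every feasible point is a tree, and the program is always
feasible.

The backend is the exact branch-and-bound solver HiGHS via
``scipy.optimize.milp``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import LinearConstraint, milp, Bounds

from .datamodel import Dataset, Pattern, ProbePanel, ProgressionTree
from .errors import ContractError, InvariantError
from .events import DEFAULT_FLOOR


@dataclass
class MergeConfig:
    """MILP penalties and solver settings (defaults rho=1000, sigma=100,
    tau=100)."""

    rho: float = 1000.0
    sigma: float = 100.0
    tau: float = 100.0
    #: weak penalty for selecting an unobserved (Steiner) pair; breaks
    #: the tie between one concerted edge and a two-step route through a
    #: gratuitous intermediate while never blocking necessary Steiner nodes
    steiner_penalty: float = 1.0
    timeout: float = 300.0
    mip_gap: float = 0.0


@dataclass
class MergeProblem:
    """A fully-specified merge instance.

    Node index 0 of each tree is its root; ``p`` holds observed joint
    frequencies normalized to sum to one; ``w_a``/``w_b`` the -log
    probability of the edge into each node (0 for the root).
    """

    tree_a: ProgressionTree
    tree_b: ProgressionTree
    nodes_a: Tuple[Pattern, ...]
    nodes_b: Tuple[Pattern, ...]
    parent_a: Tuple[int, ...]  # parent index of each A node (root: -1)
    parent_b: Tuple[int, ...]
    p: np.ndarray              # (m, n) observed joint frequencies
    w_a: np.ndarray            # (m,)
    w_b: np.ndarray            # (n,)
    rho: float
    sigma: float
    tau: float
    steiner_penalty: float
    joint_panel: ProbePanel
    joint_counts: Dict[Pattern, int] = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.nodes_a)

    @property
    def n(self) -> int:
        return len(self.nodes_b)

    def ploidy_mismatch(self, i: int, j: int) -> bool:
        return self.nodes_a[i][0] != self.nodes_b[j][0]

    def joint_state(self, i: int, j: int) -> Pattern:
        """Copy-number state of pair (i, j): A's ploidy, A genes, B genes."""
        return self.nodes_a[i] + self.nodes_b[j][1:]


@dataclass
class MergeSolution:
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    q: np.ndarray
    objective: float
    status: str  # "optimal" or "feasible"


def _index_tree(tree: ProgressionTree) -> Tuple[Tuple[Pattern, ...], Tuple[int, ...]]:
    nodes = [tree.root] + [p for p in tree.nodes() if p != tree.root]
    pos = {p: k for k, p in enumerate(nodes)}
    parents = tuple(
        -1 if p == tree.root else pos[tree.parent(p)] for p in nodes
    )
    return tuple(nodes), parents


def _edge_weights(tree: ProgressionTree, nodes: Sequence[Pattern]) -> np.ndarray:
    w = np.zeros(len(nodes))
    for k, pat in enumerate(nodes):
        if pat == tree.root:
            continue
        prob = tree.edge(pat).probability
        if prob <= 0:
            raise ContractError(f"edge into {pat} has probability {prob}")
        w[k] = -np.log(prob)
    return w


def build_merge_problem(
    tree_a: ProgressionTree,
    tree_b: ProgressionTree,
    joint_ds: Dataset,
    config: Optional[MergeConfig] = None,
) -> MergeProblem:
    """Assemble the MILP instance for two trees and the joint sample.

    The joint dataset is marginalized to the union of the two trees'
    probes; each joint pattern's marginal on either probe set must be a
    node of the corresponding tree.
    """
    config = config or MergeConfig()
    pa, pb = tree_a.panel, tree_b.panel
    if pa.ploidy_probe != pb.ploidy_probe:
        raise ContractError("trees use different ploidy probes")
    if set(pa.gene_probes) & set(pb.gene_probes):
        raise ContractError("gene probe sets must be disjoint")
    joint_panel = ProbePanel(
        pa.ploidy_probe, pa.gene_probes + pb.gene_probes, pa.max_copy
    )
    ds = joint_ds.marginalize(joint_panel.probe_names)
    # marginalize keeps the source panel's gene order; remap columns so
    # patterns follow (ploidy, A genes, B genes)
    col = [ds.panel.index_of(name) for name in joint_panel.probe_names]

    nodes_a, parent_a = _index_tree(tree_a)
    nodes_b, parent_b = _index_tree(tree_b)
    pos_a = {p: k for k, p in enumerate(nodes_a)}
    pos_b = {p: k for k, p in enumerate(nodes_b)}
    na = pa.n_genes

    p = np.zeros((len(nodes_a), len(nodes_b)))
    counts: Dict[Pattern, int] = {}
    for raw, cnt in ds.counts.items():
        pat = tuple(raw[i] for i in col)
        marg_a = (pat[0],) + pat[1:1 + na]
        marg_b = (pat[0],) + pat[1 + na:]
        if marg_a not in pos_a:
            raise ContractError(f"marginal {marg_a} of {pat} missing from tree A")
        if marg_b not in pos_b:
            raise ContractError(f"marginal {marg_b} of {pat} missing from tree B")
        p[pos_a[marg_a], pos_b[marg_b]] += cnt
        counts[pat] = cnt
    if p.sum() > 0:
        p /= p.sum()

    return MergeProblem(
        tree_a=tree_a,
        tree_b=tree_b,
        nodes_a=nodes_a,
        nodes_b=nodes_b,
        parent_a=parent_a,
        parent_b=parent_b,
        p=p,
        w_a=_edge_weights(tree_a, nodes_a),
        w_b=_edge_weights(tree_b, nodes_b),
        rho=config.rho,
        sigma=config.sigma,
        tau=config.tau,
        steiner_penalty=config.steiner_penalty,
        joint_panel=joint_panel,
        joint_counts=counts,
    )


def solve_merge(
    problem: MergeProblem, config: Optional[MergeConfig] = None
) -> Tuple[MergeSolution, ProgressionTree]:
    """Solve the merge MILP to optimality and build the merged tree.

    Pairs with no joint observation (p_ij = 0) become Steiner nodes.  The
    solution is verified against every constraint and the tree property
    before being returned.
    """
    config = config or MergeConfig()
    m, n = problem.m, problem.n
    mn = m * n

    def ia(i, j):
        return i * n + j

    # variable layout: [a (mn), b (mn), c (mn), q (mn), d (mn)]
    nvar = 5 * mn
    A_OFF, B_OFF, C_OFF, Q_OFF, D_OFF = 0, mn, 2 * mn, 3 * mn, 4 * mn

    lb = np.zeros(nvar)
    ub = np.ones(nvar)
    # fixed variables: no a/c edge into row 1, no b/c edge into column 1
    for j in range(1, n):
        ub[A_OFF + ia(0, j)] = 0.0
        ub[C_OFF + ia(0, j)] = 0.0
    for i in range(1, m):
        ub[B_OFF + ia(i, 0)] = 0.0
        ub[C_OFF + ia(i, 0)] = 0.0
    ub[A_OFF + ia(0, 0)] = 0.0
    ub[B_OFF + ia(0, 0)] = 0.0
    lb[C_OFF + ia(0, 0)] = 1.0  # c_11 = 1: the root pair always exists

    obs = problem.p > 0
    mism = np.fromfunction(
        np.vectorize(lambda i, j: problem.ploidy_mismatch(int(i), int(j))),
        (m, n),
    ).astype(bool)

    cost = np.zeros(nvar)
    for i in range(m):
        for j in range(n):
            k = ia(i, j)
            extra = (problem.rho if mism[i, j] else 0.0) - (
                problem.tau if obs[i, j] else 0.0
            ) + (0.0 if obs[i, j] else problem.steiner_penalty)
            cost[A_OFF + k] = problem.w_a[i] + extra
            cost[B_OFF + k] = problem.w_b[j] + extra
            cost[C_OFF + k] = problem.w_a[i] + problem.w_b[j] + extra
            cost[D_OFF + k] = problem.sigma
    const_term = problem.tau * int(obs.sum())

    rows: List[Dict[int, float]] = []
    lo: List[float] = []
    hi: List[float] = []

    def add(row: Dict[int, float], low: float, high: float) -> None:
        rows.append(row)
        lo.append(low)
        hi.append(high)

    inf = np.inf
    for i in range(m):
        for j in range(n):
            k = ia(i, j)
            sel = {A_OFF + k: 1.0, B_OFF + k: 1.0, C_OFF + k: 1.0}
            # at most one parent
            add(dict(sel), -inf, 1.0)
            # q_ij <= a + b + c
            row = {Q_OFF + k: 1.0}
            for v in sel:
                row[v] = -1.0
            add(row, -inf, 0.0)
            # |p - q| linearization
            add({D_OFF + k: 1.0, Q_OFF + k: 1.0}, problem.p[i, j], inf)
            add({D_OFF + k: 1.0, Q_OFF + k: -1.0}, -problem.p[i, j], inf)
            # parent constraints
            ka = problem.parent_a[i]
            kb = problem.parent_b[j]
            if i != 0:
                kp = ia(ka, j)
                add(
                    {A_OFF + k: 1.0, A_OFF + kp: -1.0, B_OFF + kp: -1.0,
                     C_OFF + kp: -1.0},
                    -inf, 0.0,
                )
            if j != 0:
                kp = ia(i, kb)
                add(
                    {B_OFF + k: 1.0, A_OFF + kp: -1.0, B_OFF + kp: -1.0,
                     C_OFF + kp: -1.0},
                    -inf, 0.0,
                )
            if i != 0 and j != 0:
                kp = ia(ka, kb)
                add(
                    {C_OFF + k: 1.0, A_OFF + kp: -1.0, B_OFF + kp: -1.0,
                     C_OFF + kp: -1.0},
                    -inf, 0.0,
                )
    # marginal sums match observations
    for i in range(m):
        add({Q_OFF + ia(i, j): 1.0 for j in range(n)},
            problem.p[i].sum(), problem.p[i].sum())
    for j in range(n):
        add({Q_OFF + ia(i, j): 1.0 for i in range(m)},
            problem.p[:, j].sum(), problem.p[:, j].sum())
    # all edges of A and B are used
    for i in range(1, m):
        add(
            {**{A_OFF + ia(i, l): 1.0 for l in range(n)},
             **{C_OFF + ia(i, l): 1.0 for l in range(n)}},
            1.0, inf,
        )
    for j in range(1, n):
        add(
            {**{B_OFF + ia(k, j): 1.0 for k in range(m)},
             **{C_OFF + ia(k, j): 1.0 for k in range(m)}},
            1.0, inf,
        )

    data, ri, ci = [], [], []
    for r, row in enumerate(rows):
        for c, v in row.items():
            ri.append(r)
            ci.append(c)
            data.append(v)
    a_mat = sparse.csr_matrix((data, (ri, ci)), shape=(len(rows), nvar))

    integrality = np.zeros(nvar)
    integrality[: 3 * mn] = 1

    res = milp(
        c=cost,
        constraints=LinearConstraint(a_mat, np.array(lo), np.array(hi)),
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options={
            "time_limit": config.timeout,
            "mip_rel_gap": config.mip_gap,
            "presolve": True,
        },
    )
    if res.x is None:
        raise InvariantError(
            f"merge MILP returned no solution (status {res.status}: {res.message})"
        )
    status = "optimal" if res.status == 0 else "feasible"

    a = np.round(res.x[A_OFF:A_OFF + mn]).reshape(m, n).astype(int)
    b = np.round(res.x[B_OFF:B_OFF + mn]).reshape(m, n).astype(int)
    c = np.round(res.x[C_OFF:C_OFF + mn]).reshape(m, n).astype(int)
    q = np.clip(res.x[Q_OFF:Q_OFF + mn].reshape(m, n), 0.0, 1.0)
    solution = MergeSolution(a, b, c, q, float(res.fun + const_term), status)

    verify_merge_solution(problem, solution)
    tree = _solution_tree(problem, solution)
    return solution, tree


def _solution_tree(problem: MergeProblem, sol: MergeSolution) -> ProgressionTree:
    """Materialize the selected pairs as a progression tree.

    Distinct index pairs can occasionally map to the same joint
    copy-number state (a ploidy-mismatched pairing against the other
    tree's root); such duplicates are collapsed onto the first state
    encountered in breadth-first order from the root pair, which keeps
    the result a connected tree.
    """
    m, n = problem.m, problem.n
    sel = sol.a + sol.b + sol.c
    pair_parent: Dict[Tuple[int, int], Tuple[int, int]] = {}
    children: Dict[Tuple[int, int], List[Tuple[int, int]]] = {}
    for i in range(m):
        for j in range(n):
            if not sel[i, j] or (i, j) == (0, 0):
                continue
            if sol.a[i, j]:
                par = (problem.parent_a[i], j)
            elif sol.b[i, j]:
                par = (i, problem.parent_b[j])
            else:
                par = (problem.parent_a[i], problem.parent_b[j])
            pair_parent[(i, j)] = par
            children.setdefault(par, []).append((i, j))

    tree = ProgressionTree(problem.joint_panel)
    root_state = problem.joint_state(0, 0)
    tree.add_node(root_state, problem.p[0, 0] > 0,
                  problem.joint_counts.get(root_state, 0))
    queue = [(0, 0)]
    while queue:
        pair = queue.pop(0)
        for chi in sorted(children.get(pair, ())):
            i, j = chi
            state = problem.joint_state(i, j)
            if state not in tree:
                tree.add_node(state, problem.p[i, j] > 0,
                              problem.joint_counts.get(state, 0))
                prob = float(
                    np.exp(-(problem.w_a[i] * (sol.a[i, j] or sol.c[i, j])
                             + problem.w_b[j] * (sol.b[i, j] or sol.c[i, j])))
                )
                tree.add_edge(problem.joint_state(*pair), state, None, prob)
            elif problem.p[i, j] > 0:
                node = tree.node(state)
                node.observed = True
                node.frequency = problem.joint_counts.get(state, node.frequency)
            queue.append(chi)
    tree.validate(strict_events=False)
    return tree


def verify_merge_solution(
    problem: MergeProblem, sol: MergeSolution, tol: float = 1e-6
) -> None:
    """Assert every printed constraint and the tree property on a solved
    instance, independently of the solver; raises InvariantError."""
    m, n = problem.m, problem.n
    a, b, c, q = sol.a, sol.b, sol.c, sol.q
    if not (set(np.unique(a)) | set(np.unique(b)) | set(np.unique(c))) <= {0, 1}:
        raise InvariantError("a/b/c not binary")
    if c[0, 0] != 1 or a[0, 0] != 0 or b[0, 0] != 0:
        raise InvariantError("root pair variables wrong")
    if a[0, 1:].any() or c[0, 1:].any():
        raise InvariantError("a/c edge into row-1 pair")
    if b[1:, 0].any() or c[1:, 0].any():
        raise InvariantError("b/c edge into column-1 pair")
    sel = a + b + c
    if (sel > 1).any():
        raise InvariantError("pair with more than one parent")
    if ((q > sel + tol)).any():
        raise InvariantError("q positive on unselected pair")
    if (q < -tol).any() or (q > 1 + tol).any():
        raise InvariantError("q out of bounds")
    for i in range(m):
        if abs(q[i].sum() - problem.p[i].sum()) > tol:
            raise InvariantError(f"row marginal mismatch at i={i}")
    for j in range(n):
        if abs(q[:, j].sum() - problem.p[:, j].sum()) > tol:
            raise InvariantError(f"column marginal mismatch at j={j}")
    for i in range(m):
        for j in range(n):
            ka, kb = problem.parent_a[i], problem.parent_b[j]
            if i != 0 and a[i, j] > sel[ka, j]:
                raise InvariantError(f"a-edge into ({i},{j}) lacks parent")
            if j != 0 and b[i, j] > sel[i, kb]:
                raise InvariantError(f"b-edge into ({i},{j}) lacks parent")
            if (i, j) != (0, 0) and c[i, j] and not sel[ka, kb]:
                raise InvariantError(f"c-edge into ({i},{j}) lacks parent")
    for i in range(1, m):
        if a[i].sum() + c[i].sum() < 1:
            raise InvariantError(f"edge of tree A into node {i} unused")
    for j in range(1, n):
        if b[:, j].sum() + c[:, j].sum() < 1:
            raise InvariantError(f"edge of tree B into node {j} unused")
    # tree property: selected pairs form a tree rooted at (0, 0)
    parent: Dict[Tuple[int, int], Tuple[int, int]] = {}
    for i in range(m):
        for j in range(n):
            if not sel[i, j] or (i, j) == (0, 0):
                continue
            if a[i, j]:
                parent[(i, j)] = (problem.parent_a[i], j)
            elif b[i, j]:
                parent[(i, j)] = (i, problem.parent_b[j])
            else:
                parent[(i, j)] = (problem.parent_a[i], problem.parent_b[j])
    for pair, par in parent.items():
        if not sel[par]:
            raise InvariantError(f"parent pair {par} of {pair} not selected")
    for start in parent:
        seen = set()
        node = start
        while node != (0, 0):
            if node in seen:
                raise InvariantError(f"cycle through pair {node}")
            seen.add(node)
            node = parent[node]


def merge_all(
    single_trees: Sequence[ProgressionTree],
    joint_ds: Dataset,
    config: Optional[MergeConfig] = None,
) -> ProgressionTree:
    """Left-fold merge of two or more trees over disjoint gene-probe sets.

    After each pairwise merge the intermediate tree is re-weighted from
    the empirical distribution of its own decomposed edge events before
    the next merge; the probe order is recorded in the result's metadata
    (merge results are order-dependent).
    """
    from .evaluate import reweight_edges, tree_event_distribution

    if len(single_trees) < 2:
        raise ContractError("need at least two trees to merge")
    config = config or MergeConfig()
    current = single_trees[0]
    order = [current.panel.gene_probes]
    statuses = []
    for nxt in single_trees[1:]:
        problem = build_merge_problem(current, nxt, joint_ds, config)
        sol, current = solve_merge(problem, config)
        statuses.append(sol.status)
        order.append(nxt.panel.gene_probes)
        dist = tree_event_distribution(current, floor=DEFAULT_FLOOR)
        current = reweight_edges(current, dist)
    current.meta["merge_order"] = [list(g) for g in order]
    current.meta["solver_status"] = statuses
    return current
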