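"""Brute-force oracles used by the merge tests: exhaustive enumeration
of the feasible MILP assignments for tiny instances, plus a random
instance generator."""

import itertools

import numpy as np
from scipy.optimize import linprog

from ploidytree import Dataset, ProbePanel, ProgressionTree
from ploidytree.events import allowed_transitions
from ploidytree.merge import MergeProblem


def enumerate_merge_objective(problem: MergeProblem) -> float:
    """Minimum objective over every feasible (a, b, c) assignment, with
    the continuous q part solved exactly by linear programming."""
    m, n = problem.m, problem.n
    p = problem.p
    obs = p > 0
    pair_options = {}
    for i in range(m):
        for j in range(n):
            if (i, j) == (0, 0):
                pair_options[(i, j)] = ["c"]
            elif i == 0:
                pair_options[(i, j)] = [None, "b"]
            elif j == 0:
                pair_options[(i, j)] = [None, "a"]
            else:
                pair_options[(i, j)] = [None, "a", "b", "c"]
    keys = sorted(pair_options)
    best = np.inf
    for combo in itertools.product(*(pair_options[k] for k in keys)):
        assign = dict(zip(keys, combo))
        sel = {k for k, v in assign.items() if v is not None}
        ok = True
        # parent constraints
        for (i, j), t in assign.items():
            if t is None:
                continue
            ka, kb = problem.parent_a[i], problem.parent_b[j]
            if t == "a" and i != 0 and (ka, j) not in sel:
                ok = False
            elif t == "b" and j != 0 and (i, kb) not in sel:
                ok = False
            elif t == "c" and (i, j) != (0, 0) and (ka, kb) not in sel:
                ok = False
            if not ok:
                break
        if not ok:
            continue
        # all edges of A and B used
        for i in range(1, m):
            if not any(assign.get((i, l)) in ("a", "c") for l in range(n)):
                ok = False
                break
        if ok:
            for j in range(1, n):
                if not any(assign.get((k, j)) in ("b", "c") for k in range(m)):
                    ok = False
                    break
        if not ok:
            continue
        lp = _q_lp_value(problem, sel)
        if lp is None:
            continue
        cost = lp
        for (i, j), t in assign.items():
            if t is None:
                if obs[i, j]:
                    cost += problem.tau
                continue
            if t == "a":
                cost += problem.w_a[i]
            elif t == "b":
                cost += problem.w_b[j]
            else:
                cost += problem.w_a[i] + problem.w_b[j]
            if problem.ploidy_mismatch(i, j):
                cost += problem.rho
            if not obs[i, j]:
                cost += problem.steiner_penalty
        best = min(best, cost)
    return best


def _q_lp_value(problem: MergeProblem, sel) -> float:
    """min sigma * sum |p - q| subject to the marginal constraints and
    q supported on the selected pairs; None if infeasible."""
    m, n = problem.m, problem.n
    mn = m * n
    # variables: q (mn) then d (mn)
    c = np.concatenate([np.zeros(mn), np.full(mn, problem.sigma)])
    bounds = []
    for i in range(m):
        for j in range(n):
            bounds.append((0.0, 1.0 if (i, j) in sel else 0.0))
    bounds += [(0.0, None)] * mn
    a_ub, b_ub = [], []
    for k in range(mn):
        row = np.zeros(2 * mn)
        row[k], row[mn + k] = 1.0, -1.0         # q - d <= p
        a_ub.append(row)
        b_ub.append(problem.p.flat[k])
        row = np.zeros(2 * mn)
        row[k], row[mn + k] = -1.0, -1.0        # -q - d <= -p
        a_ub.append(row)
        b_ub.append(-problem.p.flat[k])
    a_eq, b_eq = [], []
    for i in range(m):
        row = np.zeros(2 * mn)
        row[i * n:(i + 1) * n] = 1.0
        a_eq.append(row)
        b_eq.append(problem.p[i].sum())
    for j in range(n):
        row = np.zeros(2 * mn)
        row[j:mn:n] = 1.0
        a_eq.append(row)
        b_eq.append(problem.p[:, j].sum())
    res = linprog(
        c, A_ub=np.array(a_ub), b_ub=np.array(b_ub),
        A_eq=np.array(a_eq), b_eq=np.array(b_eq),
        bounds=bounds, method="highs",
    )
    return float(res.fun) if res.status == 0 else None


def random_tiny_tree(panel: ProbePanel, n_nodes: int, rng) -> ProgressionTree:
    """Random single-gene tree with up to ``n_nodes`` nodes and random
    edge probabilities."""
    tree = ProgressionTree(panel)
    nodes = [panel.root]
    while len(nodes) < n_nodes:
        parent = nodes[rng.integers(len(nodes))]
        succs = allowed_transitions(parent, panel)
        child, _ = succs[rng.integers(len(succs))]
        if child in tree:
            continue
        tree.add_node(child, observed=True, frequency=1)
        tree.add_edge(parent, child, None, float(rng.uniform(0.05, 0.9)))
        nodes.append(child)
    return tree


def random_merge_fixture(rng, max_nodes=3):
    """Two random tiny trees plus a consistent joint dataset."""
    pa = ProbePanel("ploidy", ("gA",))
    pb = ProbePanel("ploidy", ("gB",))
    tree_a = random_tiny_tree(pa, int(rng.integers(1, max_nodes + 1)), rng)
    tree_b = random_tiny_tree(pb, int(rng.integers(1, max_nodes + 1)), rng)
    joint_panel = ProbePanel("ploidy", ("gA", "gB"))
    pairs = [
        (a, b)
        for a in tree_a.nodes()
        for b in tree_b.nodes()
        if a[0] == b[0]  # equal ploidy: the joint state is well defined
    ]
    rng.shuffle(pairs)
    k = int(rng.integers(1, len(pairs) + 1))
    counts = {}
    for a, b in pairs[:k]:
        counts[(a[0], a[1], b[1])] = int(rng.integers(1, 40))
    ds = Dataset(joint_panel, counts)
    return tree_a, tree_b, ds
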