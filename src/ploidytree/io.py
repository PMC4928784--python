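"""Readers and writers: tab-delimited count files, DOT emission, and a
JSON tree serialization.

Two input dialects are accepted, auto-detected from the header row:

* *per-cell*: one row of probe counts per analyzed cell;
* *pattern+count*: one row per distinct pattern with a trailing ``count``
  column holding the number of cells.

Both use UTF-8, tab separation, and a header naming the probes with the
ploidy probe first.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Tuple, Union

from .datamodel import Dataset, Pattern, ProbePanel, ProgressionTree
from .errors import InputError, InvariantError

TREE_FORMAT = "ploidytree-tree"
TREE_SCHEMA_VERSION = 1


def read_dataset(
    path: Union[str, Path],
    panel: ProbePanel,
    allow_zero_ploidy: bool = False,
    clamp: bool = False,
) -> Dataset:
    """Read a tab-delimited count file into a :class:`Dataset`.

    Per-cell rows with identical patterns are aggregated.  With
    ``clamp=True`` counts above the panel cap are clamped to ``max_copy``
    instead of rejected.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    lines = path.read_text(encoding="utf-8").splitlines()
    rows = [
        (i + 1, line) for i, line in enumerate(lines) if line.strip()
    ]
    if not rows:
        raise InputError(f"{path}: empty file")
    header = [h.strip() for h in rows[0][1].split("\t")]
    expected = list(panel.probe_names)
    if header == expected:
        has_count = False
    elif (
        len(header) == len(expected) + 1
        and header[:-1] == expected
        and header[-1].lower() == "count"
    ):
        has_count = True
    else:
        raise InputError(
            f"{path}:1: header {header} does not match panel probes "
            f"{expected} (optionally followed by a 'count' column)"
        )
    n_cols = len(expected) + (1 if has_count else 0)

    counts: Dict[Pattern, int] = {}
    body = rows[1:]
    if not body:
        raise InputError(f"{path}: no data rows")
    for lineno, line in body:
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) != n_cols:
            raise InputError(
                f"{path}:{lineno}: expected {n_cols} columns, got {len(fields)}"
            )
        try:
            values = [int(f) for f in fields]
        except ValueError:
            raise InputError(f"{path}:{lineno}: non-integer field") from None
        pat_vals = values[: len(expected)]
        cnt = values[-1] if has_count else 1
        if has_count and cnt < 1:
            raise InputError(f"{path}:{lineno}: count must be >= 1")
        if clamp:
            pat_vals = [min(v, panel.max_copy) for v in pat_vals]
        try:
            pat = panel.validate_pattern(pat_vals, allow_zero_ploidy)
        except InputError as exc:
            raise InputError(f"{path}:{lineno}: {exc}") from None
        counts[pat] = counts.get(pat, 0) + cnt
    return Dataset(panel, counts, sample_id=path.stem)


def write_dataset(
    ds: Dataset, path: Union[str, Path], dialect: str = "pattern_count"
) -> None:
    """Write a dataset in either accepted dialect."""
    path = Path(path)
    lines = []
    if dialect == "pattern_count":
        lines.append("\t".join(ds.panel.probe_names) + "\tcount")
        for pat in ds.patterns:
            lines.append("\t".join(map(str, pat)) + f"\t{ds.counts[pat]}")
    elif dialect == "per_cell":
        lines.append("\t".join(ds.panel.probe_names))
        for pat in ds.patterns:
            lines.extend(["\t".join(map(str, pat))] * ds.counts[pat])
    else:
        raise InputError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _node_id(pattern: Pattern) -> str:
    return ",".join(map(str, pattern))


def write_dot(tree: ProgressionTree) -> str:
    """Emit a tree as a GraphViz DOT digraph.

    Node labels are comma-separated copy numbers; Steiner (unobserved)
    nodes are drawn with dashed outlines; edge labels give the event
    probability to three decimals.
    """
    out = ["digraph progression {"]
    for pat in tree.nodes():
        attrs = [f'label="{_node_id(pat)}"']
        if tree.is_steiner(pat):
            attrs.append("style=dashed")
        out.append(f'  "{_node_id(pat)}" [{", ".join(attrs)}];')
    for par, chi, edge in tree.edges():
        out.append(
            f'  "{_node_id(par)}" -> "{_node_id(chi)}" '
            f'[label="{edge.probability:.3f}"];'
        )
    out.append("}")
    return "\n".join(out) + "\n"


def serialize_tree(tree: ProgressionTree) -> str:
    """Lossless JSON serialization of a progression tree."""
    doc = {
        "format": TREE_FORMAT,
        "version": TREE_SCHEMA_VERSION,
        "panel": {
            "ploidy_probe": tree.panel.ploidy_probe,
            "gene_probes": list(tree.panel.gene_probes),
            "max_copy": tree.panel.max_copy,
        },
        "meta": tree.meta,
        "nodes": [
            {
                "pattern": list(pat),
                "observed": tree.node(pat).observed,
                "frequency": tree.node(pat).frequency,
            }
            for pat in tree.nodes()
        ],
        "edges": [
            {
                "parent": list(par),
                "child": list(chi),
                "events": [list(e) for e in edge.events],
                "probability": edge.probability,
            }
            for par, chi, edge in tree.edges()
        ],
    }
    return json.dumps(doc, indent=1)


def deserialize_tree(text: str) -> ProgressionTree:
    """Parse :func:`serialize_tree` output; the result is validated
    against all progression-tree invariants."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise InputError(f"not valid JSON: {exc}") from None
    if doc.get("format") != TREE_FORMAT:
        raise InputError("not a serialized progression tree")
    if doc.get("version") != TREE_SCHEMA_VERSION:
        raise InputError(
            f"unsupported schema version {doc.get('version')!r}"
        )
    p = doc["panel"]
    panel = ProbePanel(p["ploidy_probe"], tuple(p["gene_probes"]), p["max_copy"])
    tree = ProgressionTree(panel, meta=doc.get("meta", {}))
    for nd in doc["nodes"]:
        tree.add_node(nd["pattern"], nd["observed"], nd["frequency"])
    known = set(tree.nodes())
    for ed in doc["edges"]:
        par, chi = tuple(ed["parent"]), tuple(ed["child"])
        if par not in known or chi not in known:
            raise InputError(f"edge {par}->{chi} references a missing node")
        tree.add_edge(par, chi, ed["events"], ed["probability"])
    try:
        tree.validate(strict_events=False)
    except InvariantError as exc:
        raise InputError(f"serialized tree violates invariants: {exc}") from None
    return tree


def save_tree(tree: ProgressionTree, path: Union[str, Path]) -> None:
    Path(path).write_text(serialize_tree(tree), encoding="utf-8")


def load_tree(path: Union[str, Path]) -> ProgressionTree:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    return deserialize_tree(path.read_text(encoding="utf-8"))
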