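"""Rooted, fully-labelled haplogroup phylogenies.

The haplogroup namespace is a rooted tree T whose L nodes (internal and
leaf alike) are named haplogroups.  Every node must carry a unique,
non-empty label; nodes are stored in a deterministic preorder so that the
same tree always yields the same node order, which downstream matrices
rely on.

Two interchange formats are supported:

* Newick with mandatory internal-node labels, e.g. ``(A,B)R;``
* a two-column parent-child TSV (``child<TAB>parent``, root parent ``-``)
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .errors import (
    DuplicateLabelError,
    MalformedTreeError,
    MissingLabelError,
    UnknownNodeError,
)

__all__ = ["HaplogroupTree", "parse_tree", "load_tree", "leaf_set"]


@dataclass
class HaplogroupTree:
    """A validated rooted tree over haplogroup labels.

    Attributes
    ----------
    labels:
        All L node labels in preorder (root first, children in input order).
    parent:
        ``parent[i]`` is the preorder index of node i's parent, -1 at the root.
    children:
        ``children[i]`` lists the preorder indices of node i's children.
    """

    labels: list[str]
    parent: np.ndarray
    children: list[list[int]]
    index: dict[str, int] = field(init=False, repr=False)
    _leaf_mask: np.ndarray = field(init=False, repr=False)
    _desc_mask: np.ndarray | None = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self.index = {lab: i for i, lab in enumerate(self.labels)}
        self._leaf_mask = np.array([len(c) == 0 for c in self.children])

    # -- basic accessors ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        """Total node count L (leaves + internal)."""
        return len(self.labels)

    @property
    def leaf_labels(self) -> list[str]:
        """Leaf labels in preorder."""
        return [lab for lab, is_leaf in zip(self.labels, self._leaf_mask) if is_leaf]

    @property
    def leaf_indices(self) -> np.ndarray:
        return np.flatnonzero(self._leaf_mask)

    @property
    def root(self) -> str:
        return self.labels[int(np.flatnonzero(self.parent == -1)[0])]

    def is_leaf(self, label: str) -> bool:
        return bool(self._leaf_mask[self._idx(label)])

    def _idx(self, label: str) -> int:
        try:
            return self.index[label]
        except KeyError:
            raise UnknownNodeError(f"node label not in tree: {label!r}") from None

    # -- clades ------------------------------------------------------------

    def descendant_leaf_mask(self) -> np.ndarray:
        """Boolean (L, n_leaves) matrix: entry [i, k] is True iff leaf k lies
        in the clade below node i (a leaf belongs to its own clade)."""
        if self._desc_mask is None:
            leaves = self.leaf_indices
            leaf_col = {int(j): k for k, j in enumerate(leaves)}
            mask = np.zeros((self.n_nodes, leaves.size), dtype=bool)
            # preorder guarantees children come after parents; accumulate in
            # reverse so each node sees its children's completed rows
            for i in range(self.n_nodes - 1, -1, -1):
                if not self.children[i]:
                    mask[i, leaf_col[i]] = True
                else:
                    for c in self.children[i]:
                        mask[i] |= mask[c]
            self._desc_mask = mask
        return self._desc_mask

    def leaf_set(self, node_label: str) -> set[str]:
        """All leaf labels in the clade below ``node_label`` (inclusive of
        the node itself when it is a leaf)."""
        i = self._idx(node_label)
        leaves = self.leaf_indices
        row = self.descendant_leaf_mask()[i]
        return {self.labels[int(leaves[k])] for k in np.flatnonzero(row)}

    def ancestors(self, node_label: str) -> list[str]:
        """Labels on the path from ``node_label``'s parent up to the root."""
        i = self.parent[self._idx(node_label)]
        out = []
        while i != -1:
            out.append(self.labels[int(i)])
            i = self.parent[int(i)]
        return out

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        def render(i: int) -> str:
            if not self.children[i]:
                return self.labels[i]
            inner = ",".join(render(c) for c in self.children[i])
            return f"({inner}){self.labels[i]}"

        return render(int(np.flatnonzero(self.parent == -1)[0])) + ";"

    def to_parent_child_tsv(self) -> str:
        lines = ["#child\tparent"]
        for i, lab in enumerate(self.labels):
            p = "-" if self.parent[i] == -1 else self.labels[int(self.parent[i])]
            lines.append(f"{lab}\t{p}")
        return "\n".join(lines) + "\n"

    def write(self, path: str | Path, format: str = "newick") -> None:
        text = self.to_newick() + "\n" if format == "newick" else self.to_parent_child_tsv()
        Path(path).write_text(text)


def _build(records: list[tuple[str, str | None]]) -> HaplogroupTree:
    """Validate (label, parent_label) records and arrange them in preorder."""
    labels = [r[0] for r in records]
    for lab in labels:
        if not lab:
            raise MissingLabelError("every node must carry a non-empty label")
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise DuplicateLabelError(f"duplicate node label: {lab!r}")
        seen.add(lab)

    roots = [lab for lab, par in records if par is None]
    if len(roots) != 1:
        raise MalformedTreeError(f"expected exactly one root, found {len(roots)}")
    child_of: dict[str, list[str]] = {lab: [] for lab in labels}
    for lab, par in records:
        if par is None:
            continue
        if par not in child_of:
            raise MalformedTreeError(f"parent {par!r} of {lab!r} is not a node")
        child_of[par].append(lab)

    # preorder traversal; reachability check catches cycles / orphans
    order: list[str] = []
    stack = [roots[0]]
    while stack:
        lab = stack.pop()
        order.append(lab)
        stack.extend(reversed(child_of[lab]))
    if len(order) != len(labels):
        raise MalformedTreeError("tree contains a cycle or unreachable nodes")

    pos = {lab: i for i, lab in enumerate(order)}
    parent_lab = dict(records)
    parent = np.array(
        [-1 if parent_lab[lab] is None else pos[parent_lab[lab]] for lab in order]
    )
    children: list[list[int]] = [[] for _ in order]
    for i, p in enumerate(parent):
        if p != -1:
            children[int(p)].append(i)
    return HaplogroupTree(order, parent, children)


def _parse_newick(text: str) -> HaplogroupTree:
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises its own hierarchy
        raise MalformedTreeError(f"invalid newick: {exc}") from exc

    records: list[tuple[str, str | None]] = []
    label_of: dict[int, str] = {}
    for node in dt.preorder_node_iter():
        lab = node.taxon.label if node.taxon is not None else node.label
        if lab is None or lab == "":
            kind = "leaf" if node.is_leaf() else "internal"
            raise MissingLabelError(f"unlabelled {kind} node in newick input")
        label_of[id(node)] = lab
        par = label_of[id(node.parent_node)] if node.parent_node is not None else None
        records.append((lab, par))
    return _build(records)


def _parse_parent_child_tsv(text: str) -> HaplogroupTree:
    records: list[tuple[str, str | None]] = []
    for line in io.StringIO(text):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise MalformedTreeError(f"expected 2 tab-separated columns: {line!r}")
        child, par = parts
        records.append((child, None if par == "-" else par))
    if not records:
        raise MalformedTreeError("no node records in parent-child input")
    return _build(records)


def parse_tree(source: str, format: str = "newick") -> HaplogroupTree:
    """Parse a haplogroup tree from text.

    Parameters
    ----------
    source:
        The tree text itself (not a path).
    format:
        ``"newick"`` (internal labels mandatory) or ``"parent-child-tsv"``.
    """
    if format == "newick":
        return _parse_newick(source)
    if format in ("parent-child-tsv", "tsv"):
        return _parse_parent_child_tsv(source)
    raise ValueError(f"unknown tree format: {format!r}")


def load_tree(path: str | Path, format: str | None = None) -> HaplogroupTree:
    """Read a tree file, inferring the format from the extension when not given
    (``.nwk``/``.newick``/``.tree`` -> newick, else parent-child TSV)."""
    path = Path(path)
    if format is None:
        format = (
            "newick"
            if path.suffix.lower() in (".nwk", ".newick", ".tree", ".nhx")
            else "parent-child-tsv"
        )
    return parse_tree(path.read_text(), format)


def leaf_set(tree: HaplogroupTree, node_label: str) -> set[str]:
    """Module-level alias for :meth:`HaplogroupTree.leaf_set`."""
    return tree.leaf_set(node_label)
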