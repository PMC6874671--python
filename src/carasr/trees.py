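"""Rooted phylogenies with branch lengths.

A thin array-backed rooted tree built from Newick text (parsed with
dendropy), organized for postorder pruning sweeps.  Branch lengths are in
expected substitutions per site on the edge above each non-root node.
Multifurcations — including the polytomous root some reconstruction tools
require — are accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy


class TreeError(ValueError):
    """Raised for malformed Newick input or inconsistent tree queries."""


@dataclass
class RootedTree:
    """Rooted tree as parallel arrays indexed by node id (0 = root).

    ``parent[i]`` is the parent id (-1 for the root), ``children[i]`` the
    ordered child ids, ``length[i]`` the branch length above node ``i``
    (0.0 for the root), and ``label[i]`` the taxon label (leaves) or an
    optional internal-node label.
    """

    parent: list[int]
    children: list[list[int]]
    length: list[float]
    label: list[str | None]
    _leaf_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.parent[0] != -1 or sum(p == -1 for p in self.parent) != 1:
            raise TreeError("tree must have exactly one root at index 0")
        for i, l in enumerate(self.length):
            if not (l >= 0.0) or l != l or l == float("inf"):
                raise TreeError(f"branch length above node {i} is not finite and >= 0")
        labels = [self.label[i] for i in self.leaves()]
        if any(l is None for l in labels):
            raise TreeError("every leaf must carry a label")
        if len(set(labels)) != len(labels):
            raise TreeError("leaf labels are not unique")
        self._leaf_index = {self.label[i]: i for i in self.leaves()}

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return 0

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    def leaf_labels(self) -> list[str]:
        return [self.label[i] for i in self.leaves()]

    def leaf(self, label: str) -> int:
        try:
            return self._leaf_index[label]
        except KeyError:
            raise TreeError(f"unknown leaf label {label!r}") from None

    def postorder(self) -> list[int]:
        """Node ids, every child before its parent."""
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()
        return order

    def preorder(self) -> list[int]:
        return self.postorder()[::-1]

    def ancestors(self, i: int) -> list[int]:
        """Path from node ``i`` up to and including the root."""
        path = [i]
        while self.parent[path[-1]] != -1:
            path.append(self.parent[path[-1]])
        return path

    def total_length(self) -> float:
        return sum(self.length[1:])


def read_newick(text: str) -> RootedTree:
    """Parse a Newick string into a :class:`RootedTree`.

    The tree is taken as rooted exactly as written.  A missing branch length
    on a non-root edge, or unbalanced parentheses, raises :class:`TreeError`
    (with the character offset for bracket imbalance).
    """
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise TreeError(f"unbalanced ')' at character {pos}")
    if depth != 0:
        raise TreeError(f"unbalanced '(': {depth} unclosed at end of input")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"Newick parse error: {exc}") from exc

    parent: list[int] = []
    children: list[list[int]] = []
    length: list[float] = []
    label: list[str | None] = []

    def add(node, parent_id: int) -> int:
        nid = len(parent)
        parent.append(parent_id)
        children.append([])
        if parent_id == -1:
            length.append(0.0)
        else:
            if node.edge.length is None:
                raise TreeError("missing branch length on a non-root edge")
            length.append(float(node.edge.length))
            children[parent_id].append(nid)
        if node.taxon is not None:
            label.append(node.taxon.label)
        else:
            label.append(getattr(node, "label", None))
        for child in node.child_nodes():
            add(child, nid)
        return nid

    add(dtree.seed_node, -1)
    return RootedTree(parent, children, length, label)


def to_newick(tree: RootedTree) -> str:
    def emit(i: int) -> str:
        if tree.is_leaf(i):
            core = tree.label[i]
        else:
            core = "(" + ",".join(emit(c) for c in tree.children[i]) + ")"
            if tree.label[i]:
                core += tree.label[i]
        if i == tree.root:
            return core
        return f"{core}:{tree.length[i]:.10g}"

    return emit(tree.root) + ";"


def mrca(tree: RootedTree, labels) -> int:
    """Most recent common ancestor of a nonempty set of leaf labels."""
    labels = list(labels)
    if not labels:
        raise TreeError("mrca requires at least one leaf label")
    paths = [set(tree.ancestors(tree.leaf(l))) for l in labels]
    common = set.intersection(*paths)
    # the deepest common ancestor is the one all of whose ancestors are common
    path0 = tree.ancestors(tree.leaf(labels[0]))
    for node in path0:
        if node in common:
            return node
    raise TreeError("no common ancestor found (corrupt tree)")
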