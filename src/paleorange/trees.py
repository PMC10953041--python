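"""Dated phylogenies with extant and fossil tips.

A :class:`DatedTree` is a rooted, strictly binary tree whose nodes carry
absolute ages in Ma. Ages are derived from branch lengths at read time:
the root age equals the longest root-to-tip path, extant tips sit at age
0 and fossil tips end above 0. Newick/NEXUS parsing and writing are
delegated to dendropy.
"""

from __future__ import annotations

import io
from typing import Iterator, Sequence

import dendropy

__all__ = ["TreeNode", "DatedTree", "read_tree", "write_tree"]

EXTANT_AGE_TOL = 1e-3  # Myr; tips closer than this to the present are extant


class TreeNode:
    """One node: label, absolute age (Ma), parent/child links."""

    __slots__ = ("label", "age", "parent", "children", "index")

    def __init__(self, label: str | None = None, age: float = 0.0):
        self.label = label
        self.age = float(age)
        self.parent: TreeNode | None = None
        self.children: list[TreeNode] = []
        self.index: int = -1  # assigned by DatedTree._reindex

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def is_extant(self) -> bool:
        return self.is_tip and self.age <= EXTANT_AGE_TOL

    @property
    def branch_length(self) -> float:
        if self.parent is None:
            return 0.0
        return self.parent.age - self.age

    def __repr__(self):  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else "node"
        return f"<{kind} {self.label or self.index} @ {self.age:.3g} Ma>"


class DatedTree:
    """Rooted binary tree with node ages in Ma.

    Node indices are assigned in postorder (tips first within each
    subtree, root last) and are stable for a given topology; most numeric
    code in the package addresses nodes by index.
    """

    def __init__(self, root: TreeNode, extant_tol: float = EXTANT_AGE_TOL):
        self.root = root
        self._snap_extant(extant_tol)
        self._validate()
        self._reindex()

    # -- construction helpers --------------------------------------------

    def _snap_extant(self, tol: float) -> None:
        for node in self._walk_postorder(self.root):
            if node.is_tip and 0 <= node.age <= tol:
                node.age = 0.0

    def _validate(self) -> None:
        for node in self._walk_postorder(self.root):
            if node.age < 0:
                raise ValueError(f"node {node.label!r} has negative age {node.age}")
            if node.children and len(node.children) != 2:
                raise ValueError(
                    f"polytomy or unifurcation at node {node.label or node.age!r}: "
                    f"{len(node.children)} children (resolve before input)"
                )
            for ch in node.children:
                if ch.is_tip:
                    if ch.age > node.age + 1e-9:
                        raise ValueError(
                            f"tip {ch.label!r} older than its parent"
                        )
                elif ch.age >= node.age - 1e-12:
                    raise ValueError(
                        f"internal node age {ch.age} not strictly below parent {node.age}"
                    )

    def _reindex(self) -> None:
        self.nodes: list[TreeNode] = list(self._walk_postorder(self.root))
        for i, node in enumerate(self.nodes):
            node.index = i
        self.tip_nodes = [n for n in self.nodes if n.is_tip]
        self.internal_nodes = [n for n in self.nodes if not n.is_tip]

    @staticmethod
    def _walk_postorder(node: TreeNode) -> Iterator[TreeNode]:
        stack, out = [node], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return reversed(out)

    # -- views ------------------------------------------------------------

    def postorder(self) -> Sequence[TreeNode]:
        return self.nodes

    def preorder(self) -> list[TreeNode]:
        return list(reversed(self.nodes))

    @property
    def root_age(self) -> float:
        return self.root.age

    @property
    def n_tips(self) -> int:
        return len(self.tip_nodes)

    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tip_nodes]

    def fossil_tips(self) -> list[TreeNode]:
        return [t for t in self.tip_nodes if not t.is_extant]

    def extant_tips(self) -> list[TreeNode]:
        return [t for t in self.tip_nodes if t.is_extant]

    def tip_by_label(self, label: str) -> TreeNode:
        for t in self.tip_nodes:
            if t.label == label:
                return t
        raise KeyError(label)

    def total_branch_length(self) -> float:
        return sum(n.branch_length for n in self.nodes if n.parent is not None)

    # -- editing -----------------------------------------------------------

    def prune_tips(self, labels: set[str]) -> "DatedTree":
        """A new tree with the named tips removed (unifurcations suppressed)."""
        keep = [t.label for t in self.tip_nodes if t.label not in labels]
        if len(keep) < 2:
            raise ValueError("pruning would leave fewer than two tips")

        def build(node: TreeNode) -> TreeNode | None:
            if node.is_tip:
                if node.label in labels:
                    return None
                cp = TreeNode(node.label, node.age)
                return cp
            kids = [build(c) for c in node.children]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            cp = TreeNode(node.label, node.age)
            for k in kids:
                cp.add_child(k)
            return cp

        new_root = build(self.root)
        # suppress a degree-one root left by pruning
        while new_root is not None and len(new_root.children) == 1:
            new_root = new_root.children[0]
            new_root.parent = None
        if new_root is None or new_root.is_tip:
            raise ValueError("pruning would leave fewer than two tips")
        return DatedTree(new_root)

    def copy(self) -> "DatedTree":
        def build(node: TreeNode) -> TreeNode:
            cp = TreeNode(node.label, node.age)
            for c in node.children:
                cp.add_child(build(c))
            return cp

        return DatedTree(build(self.root))

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        def rec(node: TreeNode) -> str:
            if node.is_tip:
                core = _quote(node.label or "")
            else:
                core = "(" + ",".join(rec(c) for c in node.children) + ")"
                if node.label:
                    core += _quote(node.label)
            if node.parent is not None:
                core += f":{node.branch_length:.10g}"
            return core

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "DatedTree":
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(dtree)

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "DatedTree":
        for edge in dtree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")
        depth: dict = {dtree.seed_node: 0.0}
        maxdepth = 0.0
        for nd in dtree.preorder_node_iter():
            if nd is not dtree.seed_node:
                depth[nd] = depth[nd.parent_node] + (nd.edge.length or 0.0)
                maxdepth = max(maxdepth, depth[nd])

        def build(nd) -> TreeNode:
            label = None
            if nd.taxon is not None:
                label = nd.taxon.label
            elif nd.label:
                label = nd.label
            node = TreeNode(label, maxdepth - depth[nd])
            for c in nd.child_nodes():
                node.add_child(build(c))
            return node

        return cls(build(dtree.seed_node))


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def read_tree(path_or_text, schema: str | None = None) -> DatedTree:
    """Read a dated tree from a Newick or NEXUS file (schema auto-detected).

    Node ages are measured back from the youngest tip; tips within
    ``EXTANT_AGE_TOL`` of the present are treated as extant (age 0).
    """
    text = path_or_text
    if not str(path_or_text).lstrip().startswith(("(", "#")):
        with open(path_or_text) as fh:
            text = fh.read()
    if schema is None:
        schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
    dtree = dendropy.Tree.get(file=io.StringIO(text), schema=schema)
    return DatedTree.from_dendropy(dtree)


def write_tree(tree: DatedTree, path, schema: str = "newick") -> None:
    """Write a tree as Newick or as a minimal NEXUS TREES block."""
    newick = tree.to_newick()
    with open(path, "w") as fh:
        if schema == "newick":
            fh.write(newick + "\n")
        elif schema == "nexus":
            labels = tree.tip_labels()
            fh.write("#NEXUS\nBEGIN TAXA;\n")
            fh.write(f"  DIMENSIONS NTAX={len(labels)};\n  TAXLABELS\n")
            for lb in labels:
                fh.write(f"    {_quote(lb)}\n")
            fh.write("  ;\nEND;\nBEGIN TREES;\n")
            fh.write(f"  TREE dated = {newick}\nEND;\n")
        else:
            raise ValueError(f"unknown schema {schema!r}")
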