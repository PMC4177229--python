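"""Phylogenetic tree container shared by NJ, ML search, bootstrap and consensus.

Trees are stored rooted; an unrooted tree uses the fixed convention of a
trifurcating root. Branch lengths are non-negative; internal-node labels hold
bootstrap supports (percent, 0-100) when present. Newick parsing/serialisation
is delegated to dendropy and converted into this lightweight node structure,
which the likelihood machinery mutates in place during NNI search.
"""

from __future__ import annotations

from typing import Iterator, Optional

import dendropy


class Node:
    __slots__ = ("children", "parent", "length", "label")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.label = label
        self.length = length

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def support(self) -> Optional[float]:
        """Interpret a numeric internal-node label as a bootstrap support."""
        if self.is_leaf or self.label is None:
            return None
        try:
            return float(self.label)
        except ValueError:
            return None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def detach(self) -> "Node":
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None
        return self


class PhyloTree:
    """Rooted container; unrooted trees use a trifurcating root convention."""

    def __init__(self, root: Node):
        self.root = root

    # -- traversal -----------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    def n_leaves(self) -> int:
        return len(self.leaves())

    # -- copying / shape -----------------------------------------------------

    def copy(self) -> "PhyloTree":
        def rec(node: Node) -> Node:
            new = Node(node.label, node.length)
            for c in node.children:
                new.add(rec(c))
            return new

        return PhyloTree(rec(self.root))

    def force_trifurcation(self) -> "PhyloTree":
        """Collapse a degree-2 root into the unrooted trifurcation convention."""
        root = self.root
        while len(root.children) == 2 and self.n_leaves() >= 3:
            a, b = root.children
            keep, fold = (a, b) if not a.is_leaf else (b, a)
            if keep.is_leaf:
                break
            keep.detach()
            fold.detach()
            fold.length = (fold.length or 0.0) + (keep.length or 0.0)
            keep.add(fold)
            keep.length = None
            keep.parent = None
            root = keep
        self.root = root
        return self

    # -- bipartitions --------------------------------------------------------

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits of the unrooted tree, each as the leaf set of
        the smaller side (ties broken by lexicographic minimum)."""
        all_leaves = frozenset(self.leaf_labels())
        splits: set[frozenset] = set()
        below: dict[int, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children)
                )
        for node in self.postorder():
            if node is self.root:
                continue
            side = below[id(node)]
            other = all_leaves - side
            if len(side) < 2 or len(other) < 2:
                continue
            if len(side) < len(other) or (
                len(side) == len(other) and sorted(side) < sorted(other)
            ):
                splits.add(side)
            else:
                splits.add(other)
        return splits

    def rf_distance(self, other: "PhyloTree") -> int:
        """Robinson-Foulds symmetric difference over non-trivial splits."""
        if set(self.leaf_labels()) != set(other.leaf_labels()):
            raise ValueError("trees must share an identical leaf set")
        return len(self.bipartitions() ^ other.bipartitions())

    # -- Newick --------------------------------------------------------------

    def to_newick(self) -> str:
        def rec(node: Node) -> str:
            if node.is_leaf:
                body = node.label or ""
            else:
                body = "(" + ",".join(rec(c) for c in node.children) + ")"
                if node.label is not None:
                    body += str(node.label)
            if node.length is not None:
                body += ":%.10g" % node.length
            return body

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ValueError(f"malformed Newick: {exc}") from exc

        def rec(dnode) -> Node:
            if dnode.is_leaf():
                label = dnode.taxon.label if dnode.taxon else dnode.label
            else:
                label = dnode.label
            length = dnode.edge.length
            if length is not None and length < 0:
                raise ValueError(
                    f"negative branch length {length} on node {label!r}"
                )
            node = Node(label, length)
            for c in dnode.child_nodes():
                node.add(rec(c))
            return node

        root = rec(dtree.seed_node)
        root.length = None if root.length in (None, 0.0) else root.length
        return cls(root)


def read_newick(text: str) -> PhyloTree:
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree) -> str:
    return tree.to_newick()
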