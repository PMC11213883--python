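"""Rooted time trees: node ages in years BP, per-branch rate multipliers.

A :class:`TimeTree` is the shared currency of the package: the sampler
proposes on it, the likelihood prunes over it, and the summary/ASR modules
consume posterior collections of them.  Tips sit at age 0 unless stated
otherwise; every parent is strictly older than its children.  Serialization
goes through dendropy (Newick / NEXUS TREES blocks), with per-branch rates
carried as ``[&rate=...]`` comment annotations.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional

import dendropy

__all__ = ["Node", "TimeTree", "TreeStructureError"]


class TreeStructureError(ValueError):
    """Raised when a tree violates the rooted-binary / age-order contract."""


class Node:
    __slots__ = ("children", "parent", "age", "rate", "label", "support", "index")

    def __init__(self, label: Optional[str] = None, age: float = 0.0,
                 rate: float = 1.0) -> None:
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.age = float(age)
        self.rate = float(rate)
        self.label = label
        self.support: Optional[float] = None
        self.index: int = -1

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label or '*'}, age={self.age:.4g})"


class TimeTree:
    """Rooted binary tree with node ages (years BP) and branch rate multipliers.

    The branch leading *into* a node is identified with that node; its
    duration is ``parent.age - node.age`` and its rate multiplier is
    ``node.rate`` (unused, and conventionally 1.0, on the root).
    """

    def __init__(self, root: Node) -> None:
        self.root = root
        self._index()

    # ------------------------------------------------------------------ build
    def _index(self) -> None:
        self._postorder: list[Node] = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                self._postorder.append(node)
            else:
                stack.append((node, True))
                for c in node.children:
                    stack.append((c, False))
        for i, node in enumerate(self._postorder):
            node.index = i

    def invalidate(self) -> None:
        """Re-index after a structural edit (topology moves call this)."""
        self._index()

    # ------------------------------------------------------------- traversal
    def postorder(self) -> list[Node]:
        return self._postorder

    def preorder(self) -> list[Node]:
        return self._postorder[::-1]

    @property
    def tips(self) -> list[Node]:
        return [n for n in self._postorder if n.is_leaf]

    @property
    def internal_nodes(self) -> list[Node]:
        return [n for n in self._postorder if not n.is_leaf]

    @property
    def taxa(self) -> list[str]:
        return sorted(t.label for t in self.tips)

    @property
    def n_tips(self) -> int:
        return sum(1 for n in self._postorder if n.is_leaf)

    def tip(self, label: str) -> Node:
        for t in self.tips:
            if t.label == label:
                return t
        raise KeyError(f"no tip labelled {label!r}")

    def branch_duration(self, node: Node) -> float:
        if node.parent is None:
            return 0.0
        return node.parent.age - node.age

    @property
    def total_length(self) -> float:
        return sum(self.branch_duration(n) for n in self._postorder
                   if n.parent is not None)

    # ------------------------------------------------------------ clade math
    def clade_leafsets(self) -> dict[int, frozenset[str]]:
        """Map node index -> frozenset of descendant tip labels."""
        out: dict[int, frozenset[str]] = {}
        for node in self._postorder:
            if node.is_leaf:
                out[node.index] = frozenset([node.label])
            else:
                acc: frozenset[str] = frozenset()
                for c in node.children:
                    acc |= out[c.index]
                out[node.index] = acc
        return out

    def mrca(self, labels: Iterable[str]) -> Node:
        want = frozenset(labels)
        unknown = want - frozenset(t.label for t in self.tips)
        if unknown:
            raise KeyError(f"unknown taxa: {sorted(unknown)}")
        leafsets = self.clade_leafsets()
        best: Optional[Node] = None
        for node in self._postorder:
            if want <= leafsets[node.index]:
                if best is None or len(leafsets[node.index]) < len(leafsets[best.index]):
                    best = node
        assert best is not None
        return best

    def is_clade(self, labels: Iterable[str]) -> bool:
        want = frozenset(labels)
        node = self.mrca(want)
        return frozenset(t.label for t in _subtree_tips(node)) == want

    # -------------------------------------------------------------- validate
    def validate(self) -> None:
        seen: set[str] = set()
        for node in self._postorder:
            if node.is_leaf:
                if node.label is None:
                    raise TreeStructureError("unlabelled tip")
                if node.label in seen:
                    raise TreeStructureError(f"duplicate tip label {node.label!r}")
                seen.add(node.label)
            else:
                if len(node.children) != 2:
                    raise TreeStructureError(
                        f"non-binary node with {len(node.children)} children")
            if node.parent is not None and not node.parent.age > node.age:
                raise TreeStructureError(
                    f"parent age {node.parent.age} not greater than child age {node.age}")
            if node.rate <= 0:
                raise TreeStructureError("non-positive branch rate")

    # ------------------------------------------------------------------ copy
    def copy(self) -> "TimeTree":
        def clone(node: Node) -> Node:
            c = Node(node.label, node.age, node.rate)
            c.support = node.support
            for ch in node.children:
                c.add_child(clone(ch))
            return c
        return TimeTree(clone(self.root))

    # ------------------------------------------------------------------- i/o
    def to_dendropy(self, taxon_namespace: Optional[dendropy.TaxonNamespace] = None,
                    annotate_rates: bool = True) -> dendropy.Tree:
        tns = taxon_namespace or dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=tns)

        def build(node: Node, dnode: dendropy.Node) -> None:
            if node.is_leaf:
                dnode.taxon = tns.require_taxon(label=node.label)
            if node.parent is not None:
                dnode.edge.length = node.parent.age - node.age
                if annotate_rates:
                    dnode.annotations.add_new("rate", repr(node.rate))
            if node.support is not None:
                dnode.annotations.add_new("posterior", repr(node.support))
            for c in node.children:
                build(c, dnode.new_child())

        build(self.root, dtree.seed_node)
        return dtree

    def newick(self, annotate_rates: bool = True) -> str:
        dtree = self.to_dendropy(annotate_rates=annotate_rates)
        return dtree.as_string(schema="newick", suppress_rooting=True,
                               suppress_annotations=False,
                               unquoted_underscores=True).strip()

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "TimeTree":
        def build(dnode: dendropy.Node) -> Node:
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = Node(label=label)
            rate = dnode.annotations.get_value("rate")
            if rate is not None:
                node.rate = float(rate)
            post = dnode.annotations.get_value("posterior")
            if post is not None:
                node.support = float(post)
            for dchild in dnode.child_nodes():
                node.add_child(build(dchild))
            return node

        root = build(dtree.seed_node)
        # edge lengths -> ages, assuming contemporaneous tips at age 0
        depths: dict[dendropy.Node, float] = {}

        def set_depth(dnode: dendropy.Node, depth: float) -> None:
            depths[dnode] = depth
            for dchild in dnode.child_nodes():
                set_depth(dchild, depth + (dchild.edge.length or 0.0))

        set_depth(dtree.seed_node, 0.0)
        height = max(depths.values())

        nodes_pairs: list[tuple[Node, dendropy.Node]] = []

        def pair(node: Node, dnode: dendropy.Node) -> None:
            nodes_pairs.append((node, dnode))
            for c, dc in zip(node.children, dnode.child_nodes()):
                pair(c, dc)

        pair(root, dtree.seed_node)
        for node, dnode in nodes_pairs:
            node.age = height - depths[dnode]
            if node.is_leaf and abs(node.age) < 1e-9 * max(height, 1.0):
                node.age = 0.0
        return cls(root)

    @classmethod
    def from_newick(cls, newick: str) -> "TimeTree":
        dtree = dendropy.Tree.get(data=newick, schema="newick",
                                  suppress_internal_node_taxa=True,
                                  extract_comment_metadata=True)
        return cls.from_dendropy(dtree)


def _subtree_tips(node: Node) -> Iterator[Node]:
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            yield n
        else:
            stack.extend(n.children)


def write_nexus_trees(trees: Iterable[TimeTree], path: str,
                      annotate_rates: bool = True) -> None:
    """Write a posterior tree collection as a NEXUS TREES block."""
    tns = dendropy.TaxonNamespace()
    tlist = dendropy.TreeList(taxon_namespace=tns)
    for t in trees:
        tlist.append(t.to_dendropy(taxon_namespace=tns, annotate_rates=annotate_rates))
    tlist.write(path=path, schema="nexus", suppress_annotations=False,
                unquoted_underscores=True)


def read_nexus_trees(path: str) -> list[TimeTree]:
    tlist = dendropy.TreeList.get(path=path, schema="nexus",
                                  extract_comment_metadata=True)
    return [TimeTree.from_dendropy(t) for t in tlist]
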