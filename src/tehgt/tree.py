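"""Phylogenetic trees: a light node-linked structure with Newick in/out.

Trees may be rooted or (after neighbor joining) carry a trifurcating
root standing in for an unrooted tree.  Branch lengths are non-negative
floats; internal nodes may carry integer bootstrap supports in [0, 100],
serialized as internal-node labels.
"""

from __future__ import annotations

import itertools
from typing import Callable, Iterable, Iterator, Optional

import numpy as np


class Node:
    __slots__ = ("label", "length", "support", "children", "parent")

    def __init__(
        self,
        label: str | None = None,
        length: float | None = None,
        support: int | None = None,
    ):
        self.label = label
        self.length = length
        self.support = support
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> frozenset[str]:
        return frozenset(n.label for n in self.leaves())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.label or '*'} len={self.length}>"


class NewickError(ValueError):
    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class PhyloTree:
    """Rooted view of a phylogenetic tree; see module docstring."""

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    def _validate(self) -> None:
        names = [n.label for n in self.root.leaves()]
        if len(names) != len(set(names)):
            dup = sorted({x for x in names if names.count(x) > 1})
            raise ValueError(f"duplicate leaf labels: {dup}")
        for node in self.root.postorder():
            if node.length is not None and node.length < 0:
                raise ValueError(f"negative branch length on {node.label!r}")
            if node.support is not None and not (0 <= node.support <= 100):
                raise ValueError(f"support {node.support} outside [0, 100]")

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, default_length: float = 1.0) -> "PhyloTree":
        """Parse a Newick string; missing branch lengths default to 1.0.

        Malformed input raises :class:`NewickError` carrying the
        character offset of the problem.
        """
        text = text.strip()
        if not text:
            raise NewickError("empty Newick string", 0)
        if not text.endswith(";"):
            raise NewickError("missing terminating semicolon", len(text))
        pos = 0

        def error(msg: str) -> NewickError:
            return NewickError(msg, pos)

        def parse_label() -> str:
            nonlocal pos
            start = pos
            while pos < len(text) and text[pos] not in "(),:;":
                pos += 1
            return text[start:pos].strip()

        def parse_length() -> float | None:
            nonlocal pos
            if pos < len(text) and text[pos] == ":":
                pos += 1
                start = pos
                while pos < len(text) and text[pos] not in "(),;":
                    pos += 1
                try:
                    return float(text[start:pos])
                except ValueError:
                    raise NewickError(f"bad branch length {text[start:pos]!r}", start)
            return None

        def parse_clade() -> Node:
            nonlocal pos
            node = Node()
            if pos < len(text) and text[pos] == "(":
                pos += 1
                while True:
                    node.add_child(parse_clade())
                    if pos >= len(text):
                        raise error("unbalanced parentheses")
                    if text[pos] == ",":
                        pos += 1
                        continue
                    if text[pos] == ")":
                        pos += 1
                        break
                    raise error(f"unexpected character {text[pos]!r}")
                label = parse_label()
                if label:
                    # internal labels hold bootstrap supports when integer
                    try:
                        node.support = int(label)
                    except ValueError:
                        node.label = label
            else:
                node.label = parse_label()
                if not node.label:
                    raise error("empty leaf label")
            node.length = parse_length()
            return node

        root = parse_clade()
        if pos >= len(text) or text[pos] != ";":
            raise error("trailing characters before semicolon")
        for node in root.postorder():
            if node is not root and node.length is None:
                node.length = default_length
        tree = cls(root)
        return tree

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length, node.support)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root))

    # -- serialization ------------------------------------------------

    def to_newick(self, lengths: bool = True, digits: int = 6) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                body = node.label or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = node.label or (
                    str(node.support) if node.support is not None else ""
                )
                body = f"({inner}){label}"
            if lengths and node.length is not None and node is not self.root:
                body += f":{node.length:.{digits}g}"
            return body

        return fmt(self.root) + ";"

    # -- queries ------------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves())

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def find_leaf(self, name: str) -> Node:
        for leaf in self.root.leaves():
            if leaf.label == name:
                return leaf
        raise KeyError(name)

    def mrca(self, names: Iterable[str]) -> Node:
        wanted = frozenset(names)
        for node in self.root.postorder():
            if wanted <= node.leaf_names():
                return node
        raise KeyError(f"no common ancestor for {sorted(wanted)}")

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits of the unrooted tree, each given as the
        canonical (lexicographically smaller frozenset) side."""
        all_names = self.leaf_names()
        splits: set[frozenset[str]] = set()
        for node in self.root.postorder():
            if node is self.root or node.is_leaf:
                continue
            side = node.leaf_names()
            other = all_names - side
            if len(side) < 2 or len(other) < 2:
                continue
            splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return splits

    def is_monophyletic(self, names: Iterable[str]) -> bool:
        """True when the subset forms one side of a split of the
        unrooted tree (so a clade under some rooting)."""
        wanted = frozenset(names)
        all_names = self.leaf_names()
        if not wanted or not wanted <= all_names:
            raise ValueError("subset must be a non-empty subset of leaf labels")
        if len(wanted) in (1, len(all_names)):
            return True
        for node in self.root.postorder():
            side = node.leaf_names()
            if side == wanted or (all_names - side) == wanted:
                return True
        return False

    def node_depths(self) -> dict[Node, float]:
        """Cumulative branch length from the root to each node."""
        depths: dict[Node, float] = {self.root: 0.0}
        for node in self.root.preorder():
            if node is self.root:
                continue
            depths[node] = depths[node.parent] + (node.length or 0.0)
        return depths

    def path_distances(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf path-length matrix (labels sorted)."""
        leaves = sorted(self.root.leaves(), key=lambda n: n.label)
        labels = [n.label for n in leaves]
        depths = self.node_depths()
        ancestors: dict[Node, list[Node]] = {}
        for leaf in leaves:
            chain = []
            node = leaf
            while node is not None:
                chain.append(node)
                node = node.parent
            ancestors[leaf] = chain
        n = len(leaves)
        mat = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            chain_i = ancestors[leaves[i]]
            set_i = set(id(x) for x in chain_i)
            lca = next(x for x in ancestors[leaves[j]] if id(x) in set_i)
            d = depths[leaves[i]] + depths[leaves[j]] - 2 * depths[lca]
            mat[i, j] = mat[j, i] = d
        return labels, mat

    # -- editing ------------------------------------------------------

    def prune_leaves(self, names: Iterable[str]) -> "PhyloTree":
        """Tree with the named leaves removed; unary nodes collapsed
        (their lengths summed)."""
        drop = frozenset(names)
        keep = self.leaf_names() - drop
        if len(keep) < 2:
            raise ValueError("pruning would leave fewer than 2 leaves")

        def build(node: Node) -> Node | None:
            if node.is_leaf:
                if node.label in drop:
                    return None
                return Node(node.label, node.length, node.support)
            kids = [build(c) for c in node.children]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                child = kids[0]
                child.length = (child.length or 0.0) + (node.length or 0.0)
                return child
            new = Node(node.label, node.length, node.support)
            for k in kids:
                new.add_child(k)
            return new

        root = build(self.root)
        if root is None:
            raise ValueError("pruned everything")
        root.length = None
        return PhyloTree(root)

    def midpoint_root(self) -> "PhyloTree":
        """Copy of the tree rerooted at the midpoint of the longest
        leaf-to-leaf path (supports are left on their original nodes)."""
        tree = self.copy()
        labels, mat = tree.path_distances()
        if len(labels) < 3:
            return tree
        i, j = np.unravel_index(int(np.argmax(mat)), mat.shape)
        diameter = mat[i, j]
        if diameter <= 0:
            return tree
        u = tree.find_leaf(labels[i])
        v = tree.find_leaf(labels[j])
        lca = tree.mrca([labels[i], labels[j]])
        target = diameter / 2.0

        def find_edge(start: Node) -> tuple[Node, float] | None:
            cum = 0.0
            node = start
            while node is not lca:
                length = node.length or 0.0
                if cum + length >= target - 1e-12:
                    return node, target - cum
                cum += length
                node = node.parent
            return None

        found = find_edge(u) or find_edge(v)
        if found is None:
            return tree
        child, dist_from_child = found
        return tree._rerooted_on_edge(child, dist_from_child)

    def _rerooted_on_edge(self, child: Node, dist_from_child: float) -> "PhyloTree":
        """Reroot (in place on this tree's nodes) on the edge above
        ``child``, ``dist_from_child`` along it; returns a new view."""
        parent = child.parent
        if parent is None:
            return self
        orig_len = child.length or 0.0
        dist_from_child = min(max(dist_from_child, 0.0), orig_len)
        new_root = Node()
        parent.children.remove(child)
        child.parent = None
        child.length = dist_from_child
        new_root.add_child(child)
        prev = new_root
        carry = orig_len - dist_from_child
        node = parent
        while node is not None:
            up = node.parent
            up_len = node.length
            if up is not None:
                up.children.remove(node)
            node.parent = None
            prev.add_child(node)
            node.length = carry
            carry = up_len
            prev = node
            node = up
        # splice any now-unary internal nodes (e.g. the old root)
        def splice(node: Node) -> None:
            for kid in list(node.children):
                splice(kid)
            if len(node.children) == 1 and node.parent is not None:
                only = node.children[0]
                only.length = (only.length or 0.0) + (node.length or 0.0)
                idx = node.parent.children.index(node)
                node.parent.children[idx] = only
                only.parent = node.parent

        splice(new_root)
        if len(new_root.children) == 1:
            new_root = new_root.children[0]
            new_root.parent = None
            new_root.length = None
        return PhyloTree(new_root)

    def relabel(self, mapping: Callable[[str], str]) -> "PhyloTree":
        tree = self.copy()
        for leaf in tree.root.leaves():
            leaf.label = mapping(leaf.label)
        tree._validate()
        return tree


def parse_newick(text: str) -> PhyloTree:
    """Convenience alias for :meth:`PhyloTree.from_newick`."""
    return PhyloTree.from_newick(text)
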