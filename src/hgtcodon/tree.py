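"""Rooted phylogenetic trees with named branches.

Every branch is addressed by the name of the node it leads to (its child
node), which is how downstream stages (HGT calls, residence times, tRNA
changes) refer to branches.  Internal nodes without a name in the input
Newick are assigned stable names ``N1, N2, ...`` in postorder.
"""

from __future__ import annotations

import io
from typing import Iterator

import dendropy


class TreeError(ValueError):
    pass


class Node:
    __slots__ = ("name", "length", "parent", "children")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.parent: Node | None = None
        self.children: list[Node] = []

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover
        return f"Node({self.name!r}, {self.length:g})"


class Tree:
    """A rooted tree with non-negative branch lengths and unique node names."""

    def __init__(self, root: Node):
        self.root = root
        self._index: dict[str, Node] = {}
        self._reindex()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        try:
            dt = dendropy.Tree.get(data=newick, schema="newick",
                                   preserve_underscores=True)
        except Exception as exc:
            raise TreeError(f"invalid Newick: {exc}") from exc
        root = cls._convert(dt.seed_node)
        tree = cls(root)
        return tree

    @staticmethod
    def _convert(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        node = Node(label, length)
        for child in dnode.child_nodes():
            node.add_child(Tree._convert(child))
        return node

    def _reindex(self) -> None:
        counter = 0
        self._index = {}
        for node in self.postorder():
            if node.name is None:
                counter += 1
                while f"N{counter}" in self._index:
                    counter += 1
                node.name = f"N{counter}"
            if node.name in self._index:
                raise TreeError(f"duplicate node name {node.name!r}")
            self._index[node.name] = node

    # -- traversal -----------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def tip_names(self) -> list[str]:
        return [n.name for n in self.tips()]

    def node(self, name: str) -> Node:
        try:
            return self._index[name]
        except KeyError:
            raise TreeError(f"no node named {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def branches(self) -> list[Node]:
        """All non-root nodes; each identifies the branch leading to it."""
        return [n for n in self.postorder() if n.parent is not None]

    # -- queries -------------------------------------------------------

    def depths(self) -> dict[str, float]:
        """Distance from the root to every node."""
        depth = {self.root.name: 0.0}
        for node in self.preorder():
            if node.parent is not None:
                depth[node.name] = depth[node.parent.name] + node.length
        return depth

    def height(self) -> float:
        depths = self.depths()
        return max(depths[t.name] for t in self.tips())

    def clade_tips(self, name: str) -> list[str]:
        node = self.node(name)
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.name)
            stack.extend(reversed(n.children))
        return out

    def is_descendant(self, name: str, ancestor: str) -> bool:
        node = self.node(name)
        anc = self.node(ancestor)
        while node is not None:
            if node is anc:
                return True
            node = node.parent
        return False

    def lca(self, names: list[str]) -> Node:
        if not names:
            raise TreeError("lca of an empty set")
        paths = []
        for name in names:
            node = self.node(name)
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(list(reversed(path)))
        lca = self.root
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                lca = level[0]
            else:
                break
        return lca

    # -- transforms ----------------------------------------------------

    def rescale(self, target_height: float) -> "Tree":
        """Scale all branch lengths so the maximum root-to-tip depth equals
        ``target_height``."""
        h = self.height()
        if h <= 0:
            raise TreeError("cannot rescale a zero-height tree")
        factor = target_height / h
        for node in self.postorder():
            node.length *= factor
        return self

    def copy(self) -> "Tree":
        return Tree.from_newick(self.to_newick())

    def restrict(self, tip_names: list[str]) -> "Tree":
        """The induced subtree spanning ``tip_names``, suppressing unary
        internal nodes (their branch lengths are summed).  Internal node
        names from this tree are preserved where the node survives."""
        keep = set(tip_names)
        missing = keep - {t.name for t in self.tips()}
        if missing:
            raise TreeError(f"tips not in tree: {sorted(missing)}")
        if len(keep) < 2:
            raise TreeError("restriction needs at least 2 tips")

        def build(node: Node) -> Node | None:
            if node.is_leaf:
                if node.name in keep:
                    return Node(node.name, node.length)
                return None
            kids = [c for c in (build(ch) for ch in node.children)
                    if c is not None]
            if not kids:
                return None
            if len(kids) == 1:
                kids[0].length += node.length
                return kids[0]
            new = Node(node.name, node.length)
            for k in kids:
                new.add_child(k)
            return new

        root = build(self.root)
        assert root is not None
        root.length = 0.0
        return Tree(root)

    # -- output --------------------------------------------------------

    def to_newick(self, include_internal_names: bool = True) -> str:
        buf = io.StringIO()

        def write(node: Node) -> None:
            if node.children:
                buf.write("(")
                for i, child in enumerate(node.children):
                    if i:
                        buf.write(",")
                    write(child)
                buf.write(")")
                if include_internal_names and node.name:
                    buf.write(node.name)
            else:
                buf.write(node.name or "")
            if node.parent is not None:
                buf.write(f":{node.length:.10g}")

        write(self.root)
        buf.write(";")
        return buf.getvalue()

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree({len(self.tips())} tips)"
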