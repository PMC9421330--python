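"""Phylogenetic tree container with Newick round-trip.

A light node-link tree: leaves are labelled by sequence id, branch lengths
are non-negative floats on the edge above each node, and internal nodes may
carry a support value in [0, 1] (serialized as the internal-node label, the
convention used by most tree viewers). A rooted tree has a bifurcating
root; an unrooted tree is represented with a trifurcating root.
"""

from __future__ import annotations

import io
from typing import Iterator

from Bio import Phylo


class TreeError(ValueError):
    """Raised on malformed tree input or operations."""


class Node:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(
        self,
        name: str | None = None,
        length: float | None = None,
        support: float | None = None,
    ) -> None:
        self.name = name
        self.length = length
        self.support = support
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, len={self.length}, kids={len(self.children)})"


class Tree:
    """A rooted or unrooted phylogenetic tree."""

    def __init__(self, root: Node, rooted: bool | None = None) -> None:
        self.root = root
        if rooted is None:
            rooted = len(root.children) == 2
        self.rooted = rooted
        names = [l.name for l in self.leaves()]
        if len(set(names)) != len(names):
            raise TreeError("duplicate leaf labels")

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        def walk(n: Node) -> Iterator[Node]:
            for c in n.children:
                yield from walk(c)
            yield n
        return walk(self.root)

    def preorder(self) -> Iterator[Node]:
        def walk(n: Node) -> Iterator[Node]:
            yield n
            for c in n.children:
                yield from walk(c)
        return walk(self.root)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    def find(self, name: str) -> Node:
        for n in self.postorder():
            if n.name == name:
                return n
        raise TreeError(f"no node named {name!r}")

    def label_internal(self, prefix: str = "N") -> None:
        """Assign labels N1, N2, ... to unlabelled internal nodes (preorder)."""
        k = 0
        for n in self.preorder():
            if not n.is_leaf and not n.name:
                k += 1
                n.name = f"{prefix}{k}"

    def mrca(self, names: list[str]) -> Node:
        """Most recent common ancestor of a set of leaf names."""
        want = set(names)
        missing = want - set(self.leaf_names())
        if missing:
            raise TreeError(f"leaves not in tree: {sorted(missing)}")
        best: Node | None = None
        for n in self.postorder():
            below = {l.name for l in _leaves_below(n)}
            if want <= below and (best is None or len(below) < len({l.name for l in _leaves_below(best)})):
                best = n
        return best

    # -- distances ---------------------------------------------------------

    def leaf_path_lengths(self) -> dict[tuple[str, str], float]:
        """All-pairs leaf-to-leaf path lengths (keys are sorted name pairs)."""
        dists: dict[tuple[str, str], float] = {}
        # distances from every node down to its leaves, combined at each node
        down: dict[int, list[tuple[str, float]]] = {}
        for n in self.postorder():
            if n.is_leaf:
                down[id(n)] = [(n.name, 0.0)]
                continue
            lists = []
            for c in n.children:
                lists.append([(nm, d + (c.length or 0.0)) for nm, d in down[id(c)]])
            for i in range(len(lists)):
                for j in range(i + 1, len(lists)):
                    for na, da in lists[i]:
                        for nb, db in lists[j]:
                            key = (na, nb) if na < nb else (nb, na)
                            dists[key] = da + db
            down[id(n)] = [p for lst in lists for p in lst]
        return dists

    # -- copy / newick -----------------------------------------------------

    def copy(self) -> "Tree":
        def clone(n: Node) -> Node:
            m = Node(n.name, n.length, n.support)
            for c in n.children:
                m.add(clone(c))
            return m
        return Tree(clone(self.root), rooted=self.rooted)

    def to_newick(self, *, support_decimals: int | None = None) -> str:
        """Serialize to Newick; internal supports become node labels.

        Branch lengths are written with 6 decimals. ``support_decimals``
        optionally rounds supports for display.
        """
        def fmt(n: Node, is_root: bool = False) -> str:
            if n.is_leaf:
                s = n.name or ""
            else:
                s = "(" + ",".join(fmt(c) for c in n.children) + ")"
                if n.support is not None:
                    v = n.support if support_decimals is None else round(
                        n.support, support_decimals)
                    s += f"{v:g}"
                elif n.name:
                    s += n.name
            if not is_root and n.length is not None:
                s += f":{n.length:.6f}"
            return s
        return fmt(self.root, is_root=True) + ";"

    @classmethod
    def from_newick(cls, text: str, *, rooted: bool | None = None) -> "Tree":
        """Parse a Newick string (internal numeric labels read as supports)."""
        handle = io.StringIO(text)
        try:
            bp = Phylo.read(handle, "newick")
        except Exception as exc:  # pragma: no cover - Bio error text varies
            raise TreeError(f"invalid Newick: {exc}") from exc

        def convert(cl) -> Node:
            support = cl.confidence
            name = cl.name
            if name is not None and not cl.is_terminal():
                # numeric internal label is a support value
                try:
                    support = float(name)
                    name = None
                except ValueError:
                    pass
            n = Node(name=name, length=cl.branch_length, support=support)
            for c in cl.clades:
                n.add(convert(c))
            return n

        root = convert(bp.root)
        return cls(root, rooted=rooted)

    def write(self, path, **kw) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(**kw) + "\n")

    @classmethod
    def read(cls, path, **kw) -> "Tree":
        with open(path) as fh:
            return cls.from_newick(fh.read(), **kw)

    # -- bipartitions ------------------------------------------------------

    def bipartitions(self, *, nontrivial_only: bool = True) -> list[frozenset[str]]:
        """Leaf-set splits of internal edges, each as the side not containing
        an arbitrary fixed reference leaf (so representations are canonical).

        With ``nontrivial_only`` both sides must have at least 2 leaves.
        """
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        out: list[frozenset[str]] = []
        for n in self.postorder():
            if n is self.root:
                continue
            below = frozenset(l.name for l in _leaves_below(n))
            side = below if ref not in below else all_leaves - below
            if nontrivial_only and (len(side) < 2 or len(all_leaves - side) < 2):
                continue
            if 0 < len(side) < len(all_leaves):
                out.append(side)
        return out


def _leaves_below(n: Node) -> list[Node]:
    if n.is_leaf:
        return [n]
    out: list[Node] = []
    stack = [n]
    while stack:
        m = stack.pop()
        if m.is_leaf:
            out.append(m)
        else:
            stack.extend(m.children)
    return out
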