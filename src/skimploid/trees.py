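"""Lightweight phylogenetic tree structure.

Newick parsing is delegated to dendropy; algorithms that the rest of the
package needs to control precisely (bipartitions, Robinson-Foulds, leaf
pruning, rerooting) operate on this plain node structure.
"""

from __future__ import annotations

import dendropy


class Node:
    __slots__ = ("label", "length", "children", "parent", "support", "age")

    def __init__(self, label=None, length=0.0):
        self.label = label
        self.length = float(length)
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.support: float | None = None
        self.age: float | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self):
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self

    def leaves(self):
        return [n for n in self.preorder() if n.is_leaf]


class Tree:
    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------ io
    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)

        def convert(dn) -> Node:
            label = dn.taxon.label if dn.taxon is not None else dn.label
            node = Node(label=label, length=dn.edge.length if dn.edge.length else 0.0)
            if dn.label is not None and dn.taxon is None:
                try:
                    node.support = float(dn.label)
                except ValueError:
                    pass
            for c in dn.child_nodes():
                node.add(convert(c))
            return node

        return cls(convert(dt.seed_node))

    def to_newick(self, supports: bool = False, digits: int = 6) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                body = node.label or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                tag = ""
                if supports and node.support is not None:
                    tag = f"{node.support:g}"
                elif node.label:
                    tag = node.label
                body = f"({inner}){tag}"
            return f"{body}:{node.length:.{digits}g}"

        s = fmt(self.root)
        # strip the root's meaningless branch length
        return s.rsplit(":", 1)[0] + ";"

    def copy(self) -> "Tree":
        def dup(node: Node) -> Node:
            new = Node(node.label, node.length)
            new.support = node.support
            new.age = node.age
            for c in node.children:
                new.add(dup(c))
            return new

        return Tree(dup(self.root))

    # ------------------------------------------------------------- queries
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.root.leaves()]

    def find(self, label: str) -> Node:
        for n in self.root.preorder():
            if n.label == label:
                return n
        raise KeyError(f"node {label!r} not in tree")

    def has_leaf(self, label: str) -> bool:
        return any(n.label == label for n in self.root.leaves())

    def label_internal(self, prefix: str = "n") -> None:
        """Deterministically label unlabeled internal nodes (preorder)."""
        i = 0
        for node in self.root.preorder():
            if not node.is_leaf and not node.label:
                node.label = f"{prefix}{i}"
                i += 1

    def is_descendant(self, label: str, ancestor_label: str) -> bool:
        node = self.find(label)
        while node is not None:
            if node.label == ancestor_label:
                return True
            node = node.parent
        return False

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial unrooted bipartitions, each stored as the side not
        containing the lexicographically smallest leaf label."""
        leaves = set(self.leaf_labels())
        ref = min(leaves)
        out = set()
        for node in self.root.preorder():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(n.label for n in node.leaves())
            if ref in side:
                side = frozenset(leaves - side)
            if 2 <= len(side) <= len(leaves) - 2:
                out.add(side)
        return out

    # ----------------------------------------------------------- mutation
    def prune_leaf(self, label: str) -> None:
        node = self.find(label)
        if not node.is_leaf:
            raise ValueError(f"{label!r} is not a leaf")
        parent = node.parent
        if parent is None:
            raise ValueError("cannot prune the root")
        parent.children.remove(node)
        self._suppress_unifurcations()

    def _suppress_unifurcations(self) -> None:
        changed = True
        while changed:
            changed = False
            for node in list(self.root.preorder()):
                if node.is_leaf or len(node.children) != 1:
                    continue
                child = node.children[0]
                if node is self.root:
                    child.parent = None
                    child.length = 0.0
                    self.root = child
                else:
                    child.length += node.length
                    parent = node.parent
                    idx = parent.children.index(node)
                    parent.children[idx] = child
                    child.parent = parent
                changed = True
                break

    def reroot_on_edge(self, child: Node, dist_below_parent: float) -> None:
        """Place a new root on the edge above ``child``.

        ``dist_below_parent`` is the distance from the old parent end of
        the edge to the new root; the remainder stays on the child side.
        """
        old_parent = child.parent
        if old_parent is None:
            raise ValueError("node has no parent edge")
        edge_len = child.length
        dist_below_parent = min(max(dist_below_parent, 0.0), edge_len)

        old_parent.children.remove(child)
        child.parent = None

        # reverse the chain from old_parent up to the old root
        path = []
        node = old_parent
        while node is not None:
            path.append(node)
            node = node.parent
        orig_len = [n.length for n in path]
        for i in range(len(path) - 1, 0, -1):
            path[i].children.remove(path[i - 1])
        for i in range(len(path) - 1):
            path[i].add(path[i + 1])
            path[i + 1].length = orig_len[i]  # flipped edge keeps its length
        old_parent.parent = None

        new_root = Node(label=None, length=0.0)
        child.length = edge_len - dist_below_parent
        old_parent.length = dist_below_parent
        new_root.add(child)
        new_root.add(old_parent)
        self.root = new_root
        self._suppress_unifurcations()

    # ------------------------------------------------------------ metrics
    def leaf_distances(self) -> dict:
        """Dict of dicts of path lengths between all leaf pairs."""
        leaves = self.root.leaves()
        # distance from every node to every leaf below it
        below: dict[int, dict[str, float]] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                below[id(node)] = {node.label: 0.0}
            else:
                d = {}
                for c in node.children:
                    for lab, dist in below[id(c)].items():
                        d[lab] = dist + c.length
                below[id(node)] = d
        out = {l.label: {} for l in leaves}
        for node in self.root.postorder():
            kids = node.children
            for i in range(len(kids)):
                for j in range(i + 1, len(kids)):
                    di = below[id(kids[i])]
                    dj = below[id(kids[j])]
                    for la, da in di.items():
                        for lb, db in dj.items():
                            dist = da + kids[i].length + db + kids[j].length
                            out[la][lb] = dist
                            out[lb][la] = dist
        for l in leaves:
            out[l.label][l.label] = 0.0
        return out


def robinson_foulds(t1: Tree, t2: Tree) -> int:
    """Unrooted Robinson-Foulds distance (non-trivial bipartition count)."""
    l1, l2 = set(t1.leaf_labels()), set(t2.leaf_labels())
    if l1 != l2:
        raise ValueError(f"leaf sets differ: {sorted(l1 ^ l2)}")
    b1, b2 = t1.bipartitions(), t2.bipartitions()
    return len(b1 ^ b2)
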