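"""Rooted phylogenetic trees: structure, Newick I/O and the queries the
supertree machinery is built on.

The tree model is deliberately minimal: a rooted, possibly multifurcating
tree whose leaves carry unique taxon labels and whose non-root nodes may
carry branch lengths (all of them or none — mixed annotation is rejected at
parse time).  All downstream code — proper-cluster graphs, the supertree
recursions, the distance metrics and the simulators — speaks this type.

Serialisation is canonical: children are ordered by their lexicographically
smallest descendant leaf label, so a tree's Newick form is a deterministic
function of its topology and branch lengths.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import dendropy

__all__ = [
    "TreeNode",
    "RootedTree",
    "CladeSet",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "load_trees",
    "write_newick",
    "clades",
    "is_proper_cluster",
    "lca_or_root",
    "node_depth",
    "node_root_length",
    "induce_subtree",
    "leaf",
    "merge_subtrees",
]


class NewickParseError(ValueError):
    """Malformed Newick input."""


class TreeValidationError(ValueError):
    """Structurally invalid tree (duplicate labels, mixed branch lengths...)."""


class TreeNode:
    """A node of a rooted tree.  Leaves have a label and no children."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(
        self,
        label: Optional[str] = None,
        length: Optional[float] = None,
        children: Optional[list["TreeNode"]] = None,
    ) -> None:
        self.label = label
        self.length = length
        self.children: list[TreeNode] = children if children is not None else []
        self.parent: Optional[TreeNode] = None
        for child in self.children:
            child.parent = self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_leaf:
            return f"TreeNode({self.label!r})"
        return f"TreeNode(<{len(self.children)} children>)"


@dataclass(frozen=True)
class CladeSet:
    """The clades (sets of leaf labels below internal vertices) of a rooted tree.

    A clade is trivial if it is a singleton or the full leaf set; with
    ``trivial_included=False`` neither kind appears.
    """

    clades: frozenset[frozenset[str]]
    trivial_included: bool

    def __len__(self) -> int:
        return len(self.clades)

    def __iter__(self) -> Iterator[frozenset[str]]:
        return iter(self.clades)

    def __contains__(self, item: object) -> bool:
        return item in self.clades


class RootedTree:
    """A rooted (possibly multifurcating) phylogenetic tree.

    Leaf labels are taxon identities and must be unique.  Branch lengths,
    when present, are present on every non-root node.  The root never
    carries a length (it has no subtending branch).
    """

    def __init__(self, root: TreeNode, validate: bool = True) -> None:
        self.root = root
        root.parent = None
        root.length = None
        self._leaf_map: dict[str, TreeNode] = {}
        self._has_lengths: Optional[bool] = None
        self._index()
        if validate:
            self._validate()

    # -- construction helpers -------------------------------------------------

    def _index(self) -> None:
        self._leaf_map.clear()
        n_with = n_without = 0
        for node in self.iter_nodes():
            if node.is_leaf:
                if node.label is None:
                    raise TreeValidationError("leaf without a label")
                if node.label in self._leaf_map:
                    raise TreeValidationError(
                        f"duplicate leaf label {node.label!r}"
                    )
                self._leaf_map[node.label] = node
            if node is not self.root:
                if node.length is None:
                    n_without += 1
                else:
                    n_with += 1
        # fully annotated or not; partially annotated trees (e.g. supertrees
        # merged from annotated sources under unannotated new root edges)
        # count as length-free for serialisation and weighting purposes
        self._has_lengths = n_with > 0 and n_without == 0
        self._n_with_lengths = n_with
        self._n_without_lengths = n_without

    def _validate(self) -> None:
        for node in self.iter_nodes():
            if node is self.root:
                continue
            if not node.is_leaf and len(node.children) < 2:
                raise TreeValidationError(
                    "internal non-root node with fewer than 2 children"
                )
            if node.length is not None and node.length < 0:
                raise TreeValidationError(f"negative branch length {node.length}")

    # -- basic queries --------------------------------------------------------

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self._leaf_map)

    @property
    def n_taxa(self) -> int:
        return len(self._leaf_map)

    @property
    def has_branch_lengths(self) -> bool:
        return bool(self._has_lengths)

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._leaf_map

    def leaf_node(self, taxon: str) -> TreeNode:
        return self._leaf_map[taxon]

    def iter_nodes(self) -> Iterator[TreeNode]:
        """Preorder traversal (root first)."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def iter_postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def iter_leaves(self) -> Iterator[TreeNode]:
        for node in self.iter_nodes():
            if node.is_leaf:
                yield node

    # -- clades ---------------------------------------------------------------

    def leaf_sets(self) -> dict[int, frozenset[str]]:
        """Map id(node) -> leaf-label set below that node, for every node."""
        result: dict[int, frozenset[str]] = {}
        for node in self.iter_postorder():
            if node.is_leaf:
                result[id(node)] = frozenset((node.label,))
            else:
                acc: set[str] = set()
                for child in node.children:
                    acc.update(result[id(child)])
                result[id(node)] = frozenset(acc)
        return result

    def clade_set(self, include_trivial: bool = False) -> CladeSet:
        full = self.taxa
        sets = self.leaf_sets()
        out: set[frozenset[str]] = set()
        for node in self.iter_nodes():
            ls = sets[id(node)]
            trivial = len(ls) == 1 or ls == full
            if include_trivial or not trivial:
                out.add(ls)
        if include_trivial:
            out.add(full)
        return CladeSet(frozenset(out), trivial_included=include_trivial)

    # -- ancestry -------------------------------------------------------------

    def ancestors(self, node: TreeNode) -> list[TreeNode]:
        """Path from node to root, inclusive of both."""
        path = [node]
        while path[-1].parent is not None:
            path.append(path[-1].parent)
        return path

    def lca_or_root(self, u: str, v: str) -> TreeNode:
        """Lowest common ancestor when both taxa are present, else the root."""
        if u not in self._leaf_map or v not in self._leaf_map:
            return self.root
        a = self._leaf_map[u]
        b = self._leaf_map[v]
        seen = set()
        node: Optional[TreeNode] = a
        while node is not None:
            seen.add(id(node))
            node = node.parent
        node = b
        while node is not None:
            if id(node) in seen:
                return node
            node = node.parent
        raise AssertionError("nodes in the same tree must share the root")

    def is_proper_cluster(self, u: str, v: str) -> bool:
        """True iff both taxa are present and their path avoids the root."""
        if u not in self._leaf_map or v not in self._leaf_map:
            return False
        return self.lca_or_root(u, v) is not self.root

    def node_depth(self, node: TreeNode) -> int:
        """Number of edges between ``node`` and the root."""
        depth = 0
        while node.parent is not None:
            node = node.parent
            depth += 1
        return depth

    def node_root_length(self, node: TreeNode) -> float:
        """Sum of branch lengths on the root-to-node path (0.0 at the root)."""
        if node is self.root:
            return 0.0
        if not self.has_branch_lengths:
            raise TreeValidationError(
                "tree has no branch lengths; use depth weighting instead"
            )
        total = 0.0
        while node.parent is not None:
            total += node.length or 0.0
            node = node.parent
        return total

    # -- transformation -------------------------------------------------------

    def copy(self) -> "RootedTree":
        return RootedTree(_copy_node(self.root), validate=False)

    def induce(self, taxa: Iterable[str]) -> Optional["RootedTree"]:
        """The induced subtree on ``taxa`` (degree-2 chains suppressed,
        their branch lengths summed), or None if no leaf survives."""
        keep = frozenset(taxa) & self.taxa
        if not keep:
            return None
        root = _induce_node(self.root, keep)
        assert root is not None
        root.length = None
        return RootedTree(root, validate=False)

    def total_branch_length(self) -> float:
        return sum(
            node.length or 0.0 for node in self.iter_nodes() if node is not self.root
        )

    # -- serialisation --------------------------------------------------------

    def newick(self, with_lengths: bool = True) -> str:
        return write_newick(self, with_lengths=with_lengths)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.n_taxa <= 12:
            return f"RootedTree({self.newick()!r})"
        return f"RootedTree(<{self.n_taxa} taxa>)"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RootedTree):
            return NotImplemented
        return self.newick() == other.newick()

    def __hash__(self) -> int:
        return hash(self.newick())


def _copy_node(node: TreeNode) -> TreeNode:
    new = TreeNode(label=node.label, length=node.length)
    for child in node.children:
        new.add_child(_copy_node(child))
    return new


def _induce_node(node: TreeNode, keep: frozenset[str]) -> Optional[TreeNode]:
    if node.is_leaf:
        if node.label in keep:
            return TreeNode(label=node.label, length=node.length)
        return None
    kept = [c for c in (_induce_node(ch, keep) for ch in node.children) if c]
    if not kept:
        return None
    if len(kept) == 1:
        # suppress this degree-2 vertex; path length is conserved
        child = kept[0]
        if node.length is not None and child.length is not None:
            child.length = child.length + node.length
        elif node.length is not None:
            child.length = node.length
        return child
    new = TreeNode(length=node.length)
    for child in kept:
        new.add_child(child)
    return new


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> RootedTree:
    """Parse a single rooted Newick statement.

    Inner-node labels are ignored; branch lengths are captured when present.
    Unbranched (degree-2) chains are suppressed on read, summing lengths,
    so the invariant that internal non-root nodes have >= 2 children holds.
    """
    text = text.strip()
    if not text:
        raise NewickParseError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        if "duplicate" in str(exc).lower():
            raise TreeValidationError(str(exc)) from exc
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    root = _from_dendropy(dtree.seed_node)
    root = _suppress_unary(root)
    root.length = None
    tree = RootedTree(root)
    if tree._n_with_lengths and tree._n_without_lengths:
        raise TreeValidationError(
            "mixed branch-length annotation: "
            f"{tree._n_with_lengths} branches with lengths, "
            f"{tree._n_without_lengths} without"
        )
    return tree


def load_trees(path_or_text: str | io.TextIOBase, from_string: bool = False) -> list[RootedTree]:
    """Read line-separated Newick source trees from a file path or text."""
    if isinstance(path_or_text, io.TextIOBase):
        lines = path_or_text.read().splitlines()
    elif from_string:
        lines = path_or_text.splitlines()
    else:
        with open(path_or_text) as handle:
            lines = handle.read().splitlines()
    trees = []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        try:
            trees.append(parse_newick(line))
        except (NewickParseError, TreeValidationError) as exc:
            raise NewickParseError(f"line {lineno}: {exc}") from exc
    return trees


def _from_dendropy(dnode) -> TreeNode:
    if not dnode.child_nodes():
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        if label is None:
            raise NewickParseError("leaf without a label")
        return TreeNode(label=str(label), length=dnode.edge.length)
    node = TreeNode(length=dnode.edge.length)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def _suppress_unary(node: TreeNode) -> TreeNode:
    while len(node.children) == 1 and not node.is_leaf:
        child = node.children[0]
        if node.length is not None and child.length is not None:
            child.length = child.length + node.length
        elif node.length is not None:
            child.length = node.length
        child.parent = None
        node = child
    node.children = [_suppress_unary(c) for c in node.children]
    for c in node.children:
        c.parent = node
    return node


def _format_length(length: float) -> str:
    return repr(float(length))


def write_newick(tree: RootedTree, with_lengths: bool = True) -> str:
    """Canonical Newick: children ordered by smallest descendant leaf label."""
    with_lengths = with_lengths and tree.has_branch_lengths

    def render(node: TreeNode) -> tuple[str, str]:
        # returns (min descendant label, newick fragment)
        if node.is_leaf:
            frag = _escape_label(node.label)
        else:
            parts = sorted(render(c) for c in node.children)
            frag = "(" + ",".join(p[1] for p in parts) + ")"
        if with_lengths and node.length is not None:
            frag += ":" + _format_length(node.length)
        key = node.label if node.is_leaf else min(
            _min_label(c) for c in node.children
        )
        return key, frag

    return render(tree.root)[1] + ";"


def _min_label(node: TreeNode) -> str:
    if node.is_leaf:
        return node.label  # type: ignore[return-value]
    return min(_min_label(c) for c in node.children)


_NEWICK_UNSAFE = set("();,:[]' \t\n")


def _escape_label(label: str) -> str:
    if any(ch in _NEWICK_UNSAFE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Module-level functional façade
# ---------------------------------------------------------------------------


def clades(tree: RootedTree, include_trivial: bool = False) -> CladeSet:
    return tree.clade_set(include_trivial=include_trivial)


def is_proper_cluster(tree: RootedTree, u: str, v: str) -> bool:
    return tree.is_proper_cluster(u, v)


def lca_or_root(tree: RootedTree, u: str, v: str) -> TreeNode:
    return tree.lca_or_root(u, v)


def node_depth(tree: RootedTree, node: TreeNode) -> int:
    return tree.node_depth(node)


def node_root_length(tree: RootedTree, node: TreeNode) -> float:
    return tree.node_root_length(node)


def induce_subtree(tree: RootedTree, taxa: Iterable[str]) -> Optional[RootedTree]:
    return tree.induce(taxa)


def leaf(taxon: str) -> RootedTree:
    """A single-leaf tree."""
    return RootedTree(TreeNode(label=taxon))


def merge_subtrees(subtrees: Sequence[RootedTree]) -> RootedTree:
    """Connect the roots of leaf-disjoint subtrees to a new root vertex.

    A single subtree is returned unchanged.  New root edges carry no branch
    length (none is invented).
    """
    if not subtrees:
        raise ValueError("merge_subtrees requires at least one subtree")
    if len(subtrees) == 1:
        return subtrees[0]
    seen: set[str] = set()
    for st in subtrees:
        if seen & st.taxa:
            raise ValueError(
                f"overlapping leaf sets in merge: {sorted(seen & st.taxa)[:5]}"
            )
        seen |= st.taxa
    root = TreeNode()
    for st in subtrees:
        sub = _copy_node(st.root)
        sub.length = None
        root.add_child(sub)
    return RootedTree(root, validate=False)
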