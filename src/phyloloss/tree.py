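"""Rooted species trees with deterministic post-order node IDs.

The species tree is the coordinate system for every gain/loss event: loss
branches are reported as (parent_id, child_id) edges and must be comparable
across genes and across runs.  Node IDs are therefore assigned by a
deterministic post-order traversal with children kept in input (file) order,
so the same Newick string always yields the same numbering.

Branch lengths and internal-node labels are parsed but discarded: the
event-mapping model uses topology only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "SpeciesTree",
    "TreeError",
    "NewickParseError",
    "read_newick",
    "write_newick",
    "prune_tree",
]


class TreeError(ValueError):
    """Invalid tree structure (duplicate leaves, too few taxa, ...)."""


class NewickParseError(TreeError):
    """Malformed Newick input; message carries position where available."""


@dataclass(frozen=True)
class SpeciesTree:
    """Immutable rooted tree indexed by post-order node IDs.

    Node ``i``'s subtree is the contiguous ID range ``[first_desc[i], i]``,
    which makes ancestor queries and clade extraction O(1)/O(k).

    Attributes
    ----------
    parent : ndarray of int
        ``parent[i]`` is the parent node ID, ``-1`` for the root.
    children : tuple of tuple of int
        Child IDs per node, in input order; empty for leaves.
    names : tuple of str or None
        Leaf name per node; ``None`` for internal nodes.
    """

    parent: np.ndarray
    children: tuple[tuple[int, ...], ...]
    names: tuple[str | None, ...]
    first_desc: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.first_desc is None:
            fd = np.arange(self.n_nodes)
            for i, kids in enumerate(self.children):
                if kids:
                    fd[i] = fd[kids[0]]
            object.__setattr__(self, "first_desc", fd)
        self.parent.setflags(write=False)
        self.first_desc.setflags(write=False)

    # -- basic queries ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def is_leaf(self, node: int) -> bool:
        return not self.children[node]

    @property
    def leaf_ids(self) -> np.ndarray:
        """Leaf node IDs in canonical (post-order / left-to-right) order."""
        return np.array([i for i in range(self.n_nodes) if not self.children[i]])

    @property
    def leaf_names(self) -> list[str]:
        return [self.names[i] for i in self.leaf_ids]  # type: ignore[misc]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def leaf_id(self, name: str) -> int:
        try:
            return self._name_index()[name]
        except KeyError:
            raise TreeError(f"no leaf named {name!r}") from None

    def _name_index(self) -> dict[str, int]:
        idx = getattr(self, "_name_idx", None)
        if idx is None:
            idx = {self.names[i]: int(i) for i in self.leaf_ids}
            object.__setattr__(self, "_name_idx", idx)
        return idx

    def clade_leaves(self, node: int) -> list[int]:
        """Leaf IDs inside ``node``'s subtree."""
        lo = int(self.first_desc[node])
        return [i for i in range(lo, node + 1) if not self.children[i]]

    def clade_size(self, node: int) -> int:
        return len(self.clade_leaves(node))

    def is_ancestor(self, a: int, b: int, strict: bool = True) -> bool:
        """Whether node ``a`` is an ancestor of node ``b``."""
        if a == b:
            return not strict
        return self.first_desc[a] <= b <= a

    def lca(self, nodes: list[int]) -> int:
        """Lowest common ancestor of a non-empty set of nodes."""
        if not nodes:
            raise TreeError("lca of an empty node set")
        hi = max(nodes)
        v = hi
        lo = min(int(self.first_desc[n]) for n in nodes)
        while self.first_desc[v] > lo:
            v = int(self.parent[v])
        return v

    # -- construction ----------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "SpeciesTree":
        nodes = list(tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        children: list[tuple[int, ...]] = []
        names: list[str | None] = []
        for i, nd in enumerate(nodes):
            kids = tuple(index[id(c)] for c in nd.child_nodes())
            children.append(kids)
            if kids:
                names.append(None)
            else:
                label = nd.taxon.label if nd.taxon is not None else nd.label
                names.append(label)
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
        st = cls(parent=parent, children=tuple(children), names=tuple(names))
        st.validate()
        return st

    def validate(self) -> None:
        leaves = self.leaf_names
        if any(n is None or n == "" for n in leaves):
            raise TreeError("every leaf must carry a non-empty name")
        dupes = {n for n in leaves if leaves.count(n) > 1}
        if dupes:
            raise TreeError(f"duplicate leaf names: {sorted(dupes)}")
        if len(leaves) < 2:
            raise TreeError("tree must have at least 2 leaves")
        for i, kids in enumerate(self.children):
            if kids and len(kids) < 2 and i != self.root:
                raise TreeError(f"internal node {i} has a single child")

    def to_newick(self) -> str:
        def fmt(node: int) -> str:
            kids = self.children[node]
            if not kids:
                return _quote(self.names[node])  # type: ignore[arg-type]
            return "(" + ",".join(fmt(c) for c in kids) + ")"

        return fmt(self.root) + ";"


def _quote(label: str) -> str:
    if any(c in label for c in "()[]{}/\\,;:=*'\"`+<> ~\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def read_newick(text_or_path) -> SpeciesTree:
    """Parse a rooted Newick tree into a :class:`SpeciesTree`.

    Accepts a Newick string or a path to a ``.nwk`` file.  Branch lengths
    and internal labels are ignored; quoted leaf labels are supported.
    """
    text = str(text_or_path)
    if "(" not in text and ";" not in text:
        try:
            with open(text) as fh:
                text = fh.read()
        except OSError as exc:
            raise NewickParseError(f"cannot read tree input: {exc}") from exc
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    if dtree.seed_node is None or not dtree.seed_node.child_nodes():
        raise NewickParseError("malformed Newick: no tree structure found")
    return SpeciesTree.from_dendropy(dtree)


def write_newick(tree: SpeciesTree, path=None) -> str:
    """Serialize the tree; optionally write it to ``path``."""
    text = tree.to_newick()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def prune_tree(tree: SpeciesTree, keep_species) -> SpeciesTree:
    """Restrict the tree to ``keep_species``, suppressing unary nodes.

    Used for taxon-subsampling experiments: the retained leaves keep their
    names, internal nodes left with a single child are collapsed away, and
    the result is renumbered in deterministic post-order.
    """
    keep = list(dict.fromkeys(keep_species))
    names = set(tree.leaf_names)
    missing = [s for s in keep if s not in names]
    if missing:
        raise TreeError(f"species not in tree: {missing}")
    if len(keep) < 2:
        raise TreeError("need at least 2 species to prune to")
    keep_set = set(keep)

    # rebuild as nested lists, dropping excluded leaves and unary internals
    def build(node: int):
        if tree.is_leaf(node):
            name = tree.names[node]
            return name if name in keep_set else None
        kids = [build(c) for c in tree.children[node]]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return kids

    shape = build(tree.root)
    if shape is None or isinstance(shape, str):
        raise TreeError("pruning left fewer than 2 leaves")

    parent: list[int] = []
    children: list[tuple[int, ...]] = []
    out_names: list[str | None] = []

    def emit(sub) -> int:
        if isinstance(sub, str):
            parent.append(-1)
            children.append(())
            out_names.append(sub)
            return len(parent) - 1
        kid_ids = [emit(k) for k in sub]
        parent.append(-1)
        children.append(tuple(kid_ids))
        out_names.append(None)
        me = len(parent) - 1
        for k in kid_ids:
            parent[k] = me
        return me

    emit(shape)
    return SpeciesTree(
        parent=np.array(parent, dtype=np.int64),
        children=tuple(children),
        names=tuple(out_names),
    )
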