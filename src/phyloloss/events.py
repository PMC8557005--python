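"""Dollo (gain-once / lose-many) event mapping of binary profiles.

For each gene the presence/absence pattern over the leaves is mapped onto
the species tree under the Dollo assumption: the gene is gained exactly
once, at the lowest common ancestor (LCA) of its presence leaves, and may
only be lost thereafter.  Under that constraint the minimal-change
ancestral reconstruction is unique: inside the gain clade a node is in
state 1 iff at least one presence leaf descends from it, and every edge
whose parent is 1 and child is 0 is a loss event.  A loss whose child is a
leaf is a *single* loss (one species independently lost the gene); a loss
whose child is an internal node is a *continuous* loss (an entire clade of
>= 2 species lost it together).

The per-gene scan is linear in the number of tree nodes; ``node_visits``
on each annotation records the instrumented work for that contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .profile import PhyloProfile, is_aligned
from .tree import SpeciesTree

__all__ = [
    "LossBranch",
    "GainLossAnnotation",
    "gain_node",
    "ancestral_states",
    "loss_events",
    "annotate_row",
    "annotate_genome",
    "SINGLE",
    "CONTINUOUS",
]

logger = logging.getLogger(__name__)

SINGLE = "single"
CONTINUOUS = "continuous"


@dataclass(frozen=True, order=True)
class LossBranch:
    """A 1->0 transition on the tree edge ``parent_id -> child_id``."""

    child_id: int
    parent_id: int
    kind: str  # SINGLE if the lost clade is one leaf, else CONTINUOUS

    @property
    def edge(self) -> tuple[int, int]:
        return (self.parent_id, self.child_id)


@dataclass(frozen=True)
class GainLossAnnotation:
    """Per-gene Dollo reconstruction: gain node, states and loss events."""

    gene_id: str
    gain_node: int
    states: np.ndarray  # uint8 per node ID
    losses: tuple[LossBranch, ...]  # sorted by child node ID
    tree: SpeciesTree
    node_visits: int = 0

    @property
    def loss_children(self) -> frozenset[int]:
        """Loss branches keyed by child node; on a fixed tree the child
        determines the edge, so this is the set used for SCL matching."""
        return frozenset(b.child_id for b in self.losses)

    @property
    def n_losses(self) -> int:
        return len(self.losses)


def _presence_leaf_ids(tree: SpeciesTree, profile_row: np.ndarray) -> list[int]:
    row = np.asarray(profile_row)
    if row.shape != (tree.n_leaves,):
        raise ValueError(
            f"profile row has {row.shape} entries for a {tree.n_leaves}-leaf tree"
        )
    return [int(l) for l, v in zip(tree.leaf_ids, row) if v]


def gain_node(tree: SpeciesTree, profile_row) -> int:
    """The gain node: LCA of all presence leaves (the leaf itself if only
    one species carries the gene)."""
    present = _presence_leaf_ids(tree, profile_row)
    if not present:
        raise ValueError("no presence leaves: all-zero profile row")
    return tree.lca(present)


def ancestral_states(tree: SpeciesTree, profile_row, gain: int | None = None) -> np.ndarray:
    """Presence state per node under the gain-once constraint.

    State 0 everywhere outside the gain clade ("never gained"); inside it,
    1 exactly where >= 1 presence leaf descends.
    """
    ann = annotate_row(tree, profile_row, gene_id="<row>")
    if gain is not None and gain != ann.gain_node:
        raise ValueError(
            f"supplied gain node {gain} is inconsistent (computed {ann.gain_node})"
        )
    return ann.states


def loss_events(tree: SpeciesTree, states: np.ndarray) -> tuple[LossBranch, ...]:
    """Extract the 1->0 edges from a valid state assignment.

    Events are maximal by construction: a loss edge's parent has state 1,
    so no loss is nested inside another.
    """
    states = np.asarray(states)
    losses = []
    for child in range(tree.n_nodes - 1):
        p = int(tree.parent[child])
        if states[p] == 1 and states[child] == 0:
            kind = SINGLE if tree.is_leaf(child) else CONTINUOUS
            losses.append(LossBranch(child_id=child, parent_id=p, kind=kind))
    return tuple(sorted(losses))


def annotate_row(
    tree: SpeciesTree, profile_row, gene_id: str = "<row>"
) -> GainLossAnnotation:
    """Single linear scan producing gain node, states and loss events.

    One bottom-up pass accumulates presence-leaf counts per subtree; the
    gain node is the first (deepest, by post-order) node whose subtree
    holds every presence leaf, and states/losses follow from the counts
    restricted to the gain clade.
    """
    row = np.asarray(profile_row)
    if row.shape != (tree.n_leaves,):
        raise ValueError(
            f"profile row has {row.shape} entries for a {tree.n_leaves}-leaf tree"
        )
    n = tree.n_nodes
    children = tree.children
    counts = [0] * n
    visits = 0
    li = 0
    leaf_vals = row.tolist()
    total = 0
    gain = -1
    for v in range(n):
        visits += 1
        kids = children[v]
        if kids:
            c = 0
            for k in kids:
                c += counts[k]
            counts[v] = c
        else:
            counts[v] = int(leaf_vals[li])
            total += counts[v]
            li += 1
    if total == 0:
        raise ValueError(f"gene {gene_id!r}: no presence leaves (all-zero row)")
    for v in range(n):
        if counts[v] == total:
            gain = v
            break
    # states: 1 inside the gain clade wherever the subtree holds a presence
    states = np.zeros(n, dtype=np.uint8)
    lo = int(tree.first_desc[gain])
    losses = []
    parent = tree.parent
    for v in range(lo, gain + 1):
        visits += 1
        if counts[v] > 0:
            states[v] = 1
    for v in range(lo, gain):
        p = int(parent[v])
        if states[p] == 1 and states[v] == 0:
            kind = SINGLE if not children[v] else CONTINUOUS
            losses.append(LossBranch(child_id=v, parent_id=p, kind=kind))
    states.setflags(write=False)
    return GainLossAnnotation(
        gene_id=gene_id,
        gain_node=gain,
        states=states,
        losses=tuple(sorted(losses)),
        tree=tree,
        node_visits=visits,
    )


def annotate_genome(
    tree: SpeciesTree, profile: PhyloProfile
) -> dict[str, GainLossAnnotation]:
    """Annotate every gene with >= 1 presence; all-zero rows are skipped
    with a warning (the Dollo model needs at least one presence leaf)."""
    if not is_aligned(tree, profile):
        raise ValueError("profile is not aligned to the tree; call align() first")
    annotations: dict[str, GainLossAnnotation] = {}
    skipped = []
    for i, gene in enumerate(profile.gene_ids):
        row = profile.values[i]
        if not row.any():
            skipped.append(gene)
            continue
        annotations[gene] = annotate_row(tree, row, gene_id=gene)
    if skipped:
        logger.warning(
            "skipped %d all-zero gene(s) during annotation: %s",
            len(skipped),
            skipped[:10],
        )
    return annotations


def write_events_tsv(annotations: dict[str, GainLossAnnotation], path) -> None:
    """Debug dump: one row per loss branch, with the lost leaf list."""
    with open(path, "w") as fh:
        fh.write("gene\tgain_node\tparent\tchild\tkind\tlost_leaves\n")
        for gene in sorted(annotations):
            ann = annotations[gene]
            if not ann.losses:
                fh.write(f"{gene}\t{ann.gain_node}\t.\t.\t.\t.\n")
            for b in ann.losses:
                lost = ",".join(
                    ann.tree.names[l] for l in ann.tree.clade_leaves(b.child_id)
                )
                fh.write(
                    f"{gene}\t{ann.gain_node}\t{b.parent_id}\t{b.child_id}\t{b.kind}\t{lost}\n"
                )
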