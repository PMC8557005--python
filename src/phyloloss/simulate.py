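"""Synthetic trees, profiles and pathways with known gain/loss ground truth.

The generator emulates the study conditions the method targets: a rooted
species tree, a genome of binary profiles evolved under gain-once /
lose-many dynamics (each gene gained at one node, then lost along edges of
its clade with a fixed per-edge probability), and pathway gene sets whose
members share a gain node and a common core of loss branches plus small
per-gene jitter.  Per-cell flip noise emulates homology-calling errors
(missed or spurious BLAST hits).  Ground truth (membership, gain node,
pre-noise loss set) is recorded for every gene, which is what makes the
recovery and round-trip tests of the rest of the package possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .events import LossBranch, CONTINUOUS, SINGLE
from .profile import PhyloProfile
from .tree import SpeciesTree

__all__ = [
    "SimulationConfig",
    "SimTruth",
    "simulate_tree",
    "simulate_gene",
    "simulate_study",
]

logger = logging.getLogger(__name__)

_MAX_RESAMPLE = 100


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale generator settings.

    Defaults are the package's reference conditions: a 64-species tree, a
    2,000-gene background, one 20-gene pathway whose members share 3 loss
    branches with at most 1 jittered extra loss each, per-edge loss
    probability 0.1 and 1% cell flip noise.
    """

    n_species: int = 64
    n_background_genes: int = 2000
    pathway_sizes: tuple[int, ...] = (20,)
    loss_prob: float = 0.1
    shared_loss_branches: int = 3
    jitter_branches: int = 1
    flip_noise: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise ValueError("n_species must be >= 4")
        if not (0.0 <= self.loss_prob < 1.0):
            raise ValueError("loss_prob must be in [0, 1)")
        if not (0.0 <= self.flip_noise < 0.5):
            raise ValueError("flip_noise must be in [0, 0.5)")
        if self.shared_loss_branches < 0 or self.jitter_branches < 0:
            raise ValueError("branch counts must be >= 0")


@dataclass(frozen=True)
class SimTruth:
    """Pre-noise ground truth for every simulated gene."""

    membership: dict  # gene_id -> pathway_id or None (background)
    gain_node: dict  # gene_id -> node id
    losses: dict  # gene_id -> tuple[LossBranch, ...]


def simulate_tree(n_species: int, seed) -> SpeciesTree:
    """Random rooted bifurcating tree with leaves ``S1..Sn``.

    Coalescent-style: clusters are merged pairwise, uniformly at random,
    until one remains.  Bit-identical per seed.
    """
    if n_species < 4:
        raise ValueError("n_species must be >= 4")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    clusters: list = [f"S{i + 1}" for i in range(n_species)]
    while len(clusters) > 1:
        i, j = rng.choice(len(clusters), size=2, replace=False)
        i, j = int(min(i, j)), int(max(i, j))
        merged = [clusters[i], clusters[j]]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    parent: list[int] = []
    children: list[tuple[int, ...]] = []
    names: list[str | None] = []

    def emit(sub) -> int:
        if isinstance(sub, str):
            parent.append(-1)
            children.append(())
            names.append(sub)
            return len(parent) - 1
        kid_ids = [emit(k) for k in sub]
        parent.append(-1)
        children.append(tuple(kid_ids))
        names.append(None)
        me = len(parent) - 1
        for k in kid_ids:
            parent[k] = me
        return me

    emit(clusters[0])
    return SpeciesTree(
        parent=np.array(parent, dtype=np.int64),
        children=tuple(children),
        names=tuple(names),
    )


def _leaf_states_from_losses(
    tree: SpeciesTree, gain: int, loss_children
) -> np.ndarray:
    """Leaf presence vector implied by a gain node and a set of lost clades."""
    lo = int(tree.first_desc[gain])
    lost = np.zeros(tree.n_nodes, dtype=bool)
    for c in loss_children:
        lost[int(tree.first_desc[c]) : c + 1] = True
    row = np.zeros(tree.n_leaves, dtype=np.uint8)
    for li, leaf in enumerate(tree.leaf_ids):
        if lo <= leaf <= gain and not lost[leaf]:
            row[li] = 1
    return row


def _as_loss_branches(tree: SpeciesTree, loss_children) -> tuple[LossBranch, ...]:
    return tuple(
        sorted(
            LossBranch(
                child_id=c,
                parent_id=int(tree.parent[c]),
                kind=SINGLE if tree.is_leaf(c) else CONTINUOUS,
            )
            for c in loss_children
        )
    )


def _canonical_dollo(tree: SpeciesTree, row: np.ndarray) -> tuple[int, list[int]]:
    """Canonical Dollo representation of a leaf presence vector: gain =
    LCA of presence leaves, losses = maximal all-absent subtrees inside
    the gain clade.

    The generative process can leave a non-canonical event list (e.g. two
    sibling edges lost independently cover their parent's whole clade, or
    a loss beside the gain node pushes the observable origin downward);
    recorded truth is always the canonical form, because that is the only
    representation recoverable from the leaf pattern.
    """
    present = [int(l) for l, v in zip(tree.leaf_ids, row) if v]
    if not present:
        raise ValueError("all-zero row has no canonical form")
    gain = tree.lca(present)
    pset = set(present)
    lo = int(tree.first_desc[gain])
    has_presence = [False] * tree.n_nodes
    for v in range(lo, gain + 1):
        kids = tree.children[v]
        if kids:
            has_presence[v] = any(has_presence[k] for k in kids)
        else:
            has_presence[v] = v in pset
    losses = [
        v
        for v in range(lo, gain)
        if not has_presence[v] and has_presence[int(tree.parent[v])]
    ]
    return gain, losses


def simulate_gene(
    tree: SpeciesTree, gain_node: int, loss_prob: float, seed
) -> tuple[np.ndarray, tuple[LossBranch, ...]]:
    """Evolve one gene: gained at ``gain_node``, then each edge inside the
    clade loses the gene independently with ``loss_prob``.

    The returned loss set is the *canonical* event list implied by the
    surviving leaf pattern (maximal lost edges inside the LCA clade of the
    presence leaves), since that is what any reconstruction can see.  Rows
    that end up all-zero are resampled, up to a bounded number of retries.
    """
    if not 0 <= gain_node < tree.n_nodes:
        raise ValueError(f"gain node {gain_node} not in tree")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    for _ in range(_MAX_RESAMPLE):
        losses: list[int] = []

        def descend(node: int) -> None:
            for child in tree.children[node]:
                if rng.random() < loss_prob:
                    losses.append(child)
                else:
                    descend(child)

        descend(gain_node)
        row = _leaf_states_from_losses(tree, gain_node, losses)
        if row.any():
            _, canonical = _canonical_dollo(tree, row)
            return row, _as_loss_branches(tree, canonical)
    raise RuntimeError(
        f"gene at node {gain_node} came out all-zero {_MAX_RESAMPLE} times; "
        "loss_prob is too high for this clade"
    )


def _pick_pathway_core(
    tree: SpeciesTree, rng: np.random.Generator, n_shared: int
) -> tuple[int, list[int]]:
    """Choose a pathway gain node and disjoint shared loss edges that leave
    at least 2 presence leaves."""
    internal = [
        v
        for v in range(tree.n_nodes)
        if tree.children[v] and tree.clade_size(v) >= max(8, 2 * n_shared + 2)
    ]
    if not internal:
        raise ValueError("tree too small for the requested pathway structure")
    for _ in range(_MAX_RESAMPLE):
        gain = int(rng.choice(internal))
        lo = int(tree.first_desc[gain])
        candidates = [c for c in range(lo, gain)]
        rng.shuffle(candidates)
        chosen: list[int] = []
        for c in candidates:
            if len(chosen) == n_shared:
                break
            if any(
                tree.is_ancestor(c, d, strict=False) or tree.is_ancestor(d, c, strict=False)
                for d in chosen
            ):
                continue
            lost = sum(tree.clade_size(x) for x in chosen) + tree.clade_size(c)
            if tree.clade_size(gain) - lost < 2:
                continue
            chosen.append(c)
        if len(chosen) == n_shared:
            # the core must be observable as-is: losing these clades must
            # neither shift the LCA of the survivors nor merge into a
            # larger maximal loss
            row = _leaf_states_from_losses(tree, gain, chosen)
            if row.any() and _canonical_dollo(tree, row) == (gain, sorted(chosen)):
                return gain, sorted(chosen)
    raise ValueError("could not place the shared loss branches; clade too small")


def simulate_study(
    config: SimulationConfig,
) -> tuple[SpeciesTree, PhyloProfile, list[tuple[str, list[str]]], SimTruth]:
    """Generate a full study: tree, genome profile, pathways, ground truth.

    Background genes get independent random gain nodes and random losses;
    each pathway shares one gain node and a core loss set, with up to
    ``jitter_branches`` extra private losses per member.  Flip noise is
    applied last, cell-wise; truth is recorded pre-noise.

    Returns ``(tree, profile, pathways, truth)`` where ``pathways`` is a
    list of ``(pathway_id, gene_ids)`` pairs.
    """
    total_pathway = sum(config.pathway_sizes)
    if total_pathway > config.n_background_genes * 10:
        raise ValueError("pathways larger than is sensible for the genome size")
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config.n_species, rng)

    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    membership: dict = {}
    true_gain: dict = {}
    true_losses: dict = {}

    # pathways first, so their structure is independent of background count
    pathways: list[tuple[str, list[str]]] = []
    for p_idx, size in enumerate(config.pathway_sizes):
        pid = f"pw{p_idx + 1}"
        gain, core = _pick_pathway_core(tree, rng, config.shared_loss_branches)
        core_set = set(core)
        member_ids: list[str] = []
        for m in range(size):
            gid = f"{pid}_g{m + 1}"
            losses = set(core_set)
            if config.jitter_branches:
                n_extra = int(rng.integers(0, config.jitter_branches + 1))
                lo = int(tree.first_desc[gain])
                extras = [
                    c
                    for c in range(lo, gain)
                    if not any(
                        tree.is_ancestor(c, d, strict=False)
                        or tree.is_ancestor(d, c, strict=False)
                        for d in losses
                    )
                ]
                rng.shuffle(extras)
                taken = 0
                for c in extras:
                    if taken == n_extra:
                        break
                    trial = losses | {c}
                    row = _leaf_states_from_losses(tree, gain, trial)
                    if row.any() and _canonical_dollo(tree, row) == (
                        gain,
                        sorted(trial),
                    ):
                        losses = trial
                        taken += 1
            row = _leaf_states_from_losses(tree, gain, losses)
            gene_ids.append(gid)
            rows.append(row)
            member_ids.append(gid)
            membership[gid] = pid
            true_gain[gid] = gain
            true_losses[gid] = _as_loss_branches(tree, losses)
        pathways.append((pid, member_ids))

    # background: independent random gain nodes (biased away from leaves so
    # loss events can actually occur) and random per-edge losses
    internal_nodes = [v for v in range(tree.n_nodes) if tree.children[v]]
    for b in range(config.n_background_genes):
        gid = f"bg_g{b + 1}"
        gain = int(rng.choice(internal_nodes))
        row, losses = simulate_gene(tree, gain, config.loss_prob, rng)
        gene_ids.append(gid)
        rows.append(row)
        membership[gid] = None
        true_gain[gid] = _canonical_dollo(tree, row)[0]
        true_losses[gid] = losses

    values = np.stack(rows)
    if config.flip_noise > 0:
        flips = rng.random(values.shape) < config.flip_noise
        values = np.where(flips, 1 - values, values).astype(np.uint8)
        n_zeroed = int((values.sum(axis=1) == 0).sum())
        if n_zeroed:
            logger.warning("flip noise drove %d gene(s) all-zero", n_zeroed)

    profile = PhyloProfile(
        gene_ids=tuple(gene_ids),
        species_ids=tuple(tree.leaf_names),
        values=values,
    )
    truth = SimTruth(membership=membership, gain_node=true_gain, losses=true_losses)
    return tree, profile, pathways, truth
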