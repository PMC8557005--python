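"""End-to-end genome scan: annotate, classify, filter, score, rank.

Pipeline, per the three-step method:

1.  *Mapping* — every genome gene gets a Dollo gain/loss annotation.
2.  *Classify* — genome genes are partitioned among the input genes by
    naive Bayes posterior, so each input gene only scans its own bucket.
3.  *Prediction* — each candidate is kept if its gain node relates to its
    assigned input gene's gain node as the search mode demands (``same``
    by default: genes of shared function are expected to originate at the
    same common ancestor), then scored by SCL against that input gene.

The output is a single ranked list (descending SCL, ties by gene ID) of
non-input genes; input genes are the query and are excluded by default.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

from . import nbc
from .events import GainLossAnnotation, annotate_genome
from .profile import PhyloProfile, align, is_aligned, resolve_gene_set
from .scl import scl
from .tree import SpeciesTree

__all__ = [
    "GAIN_NODE_MODES",
    "PredictionRecord",
    "candidate_filter",
    "predict",
    "gain_node_histogram",
    "write_predictions_tsv",
]

logger = logging.getLogger(__name__)

#: Search modes for the gain-node filter: candidates may be required to
#: originate at the same node as the input gene, strictly earlier (an
#: ancestor), strictly later (a descendant), or any of the three.
GAIN_NODE_MODES = ("same", "earlier", "later", "both")


@dataclass(frozen=True)
class PredictionRecord:
    """One ranked candidate gene."""

    gene_id: str
    assigned_input_gene: str
    scl_value: int
    rank: int
    gain_node: int
    n_shared_losses: int
    n_unshared_losses: int


def candidate_filter(
    cand: GainLossAnnotation, ref: GainLossAnnotation, mode: str = "same"
) -> bool:
    """Does the candidate's gain node stand in the required relation to
    the reference's?

    A candidate gained at the same node always qualifies; ``earlier``
    additionally admits gains at a strict ancestor (the function appeared
    no later than the input gene's origin), ``later`` gains at a strict
    descendant, and ``both`` any of the three.  Gains in a disjoint clade
    never qualify.
    """
    if mode not in GAIN_NODE_MODES:
        raise ValueError(f"mode must be one of {GAIN_NODE_MODES}, got {mode!r}")
    if cand.tree is not ref.tree:
        raise ValueError("annotations come from different trees")
    tree = ref.tree
    g_c, g_r = cand.gain_node, ref.gain_node
    if g_c == g_r:
        return True
    if mode == "same":
        return False
    if mode == "earlier":
        return tree.is_ancestor(g_c, g_r, strict=True)
    if mode == "later":
        return tree.is_ancestor(g_r, g_c, strict=True)
    return tree.is_ancestor(g_c, g_r, strict=True) or tree.is_ancestor(
        g_r, g_c, strict=True
    )


def predict(
    tree: SpeciesTree,
    profile: PhyloProfile,
    gene_set,
    *,
    mode: str = "same",
    min_score: int | None = None,
    alpha: float = 1.0,
    include_inputs: bool = False,
    aggregate: str = "assigned",
    threads: int = 1,
    annotations: dict[str, GainLossAnnotation] | None = None,
) -> list[PredictionRecord]:
    """Rank genome genes by shared loss history with an input gene set.

    Parameters
    ----------
    tree, profile
        Species tree and binary profile (aligned automatically).
    gene_set : sequence of str
        Input gene IDs (a pathway or complex); must resolve in the profile
        and each must have >= 1 presence.
    mode : {"same", "earlier", "later", "both"}
        Gain-node search mode.
    min_score : int, optional
        Drop records with SCL below this; by default every filtered
        candidate is reported (the method has no intrinsic threshold).
    aggregate : {"assigned", "max"}
        ``assigned`` scores each candidate only against the input gene its
        NB class names (default); ``max`` scores against every input gene
        and keeps the best, for sensitivity analysis.
    threads : int
        Worker threads for the per-class scans; output is independent of
        this value (deterministic sorted merge).
    annotations : dict, optional
        Precomputed genome annotations (reused across CV repeats).

    Returns
    -------
    list of PredictionRecord, ranked 1..k.
    """
    if aggregate not in ("assigned", "max"):
        raise ValueError("aggregate must be 'assigned' or 'max'")
    if not is_aligned(tree, profile):
        profile = align(tree, profile)
    inputs, missing = resolve_gene_set(profile, gene_set)
    if not inputs:
        raise ValueError(f"no input gene resolves in the profile (missing: {missing})")
    zero_inputs = [g for g in inputs if not profile.row(g).any()]
    if zero_inputs:
        raise ValueError(f"input genes with all-zero profiles: {zero_inputs}")

    if annotations is None:
        annotations = annotate_genome(tree, profile)

    input_rows = [profile.row(g) for g in inputs]
    model = nbc.train(input_rows, gene_ids=inputs, alpha=alpha)
    assignment = nbc.classify_genome(model, profile)

    input_set = set(inputs)
    ref_anns = {g: annotations[g] for g in inputs}

    def score_one(gene: str) -> PredictionRecord | None:
        ann = annotations.get(gene)
        if ann is None:  # all-zero row, skipped at annotation
            return None
        if aggregate == "assigned":
            refs = [model.representative(assignment[gene])]
        else:
            refs = inputs
        best = None
        for ref_gene in refs:
            ref = ref_anns[ref_gene]
            if not candidate_filter(ann, ref, mode):
                continue
            s = scl(ref, ann)
            rec = (s.value, gene, ref_gene, s.shared, s.unshared)
            if best is None or rec[0] > best[0]:
                best = rec
        if best is None:
            return None
        value, gene_id, ref_gene, shared, unshared = best
        if min_score is not None and value < min_score:
            return None
        return PredictionRecord(
            gene_id=gene_id,
            assigned_input_gene=ref_gene,
            scl_value=value,
            rank=0,
            gain_node=ann.gain_node,
            n_shared_losses=shared,
            n_unshared_losses=unshared,
        )

    candidates = [
        g for g in profile.gene_ids if include_inputs or g not in input_set
    ]
    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            raw = list(pool.map(score_one, candidates))
    else:
        raw = [score_one(g) for g in candidates]
    records = [r for r in raw if r is not None]
    records.sort(key=lambda r: (-r.scl_value, r.gene_id))
    return [
        PredictionRecord(
            gene_id=r.gene_id,
            assigned_input_gene=r.assigned_input_gene,
            scl_value=r.scl_value,
            rank=i + 1,
            gain_node=r.gain_node,
            n_shared_losses=r.n_shared_losses,
            n_unshared_losses=r.n_unshared_losses,
        )
        for i, r in enumerate(records)
    ]


def gain_node_histogram(
    annotations: dict[str, GainLossAnnotation], gene_set
) -> dict[int, int]:
    """Count input genes per gain node (how a pathway clusters over the
    tree's ancestors)."""
    hist: dict[int, int] = {}
    for g in gene_set:
        if g in annotations:
            node = annotations[g].gain_node
            hist[node] = hist.get(node, 0) + 1
    return hist


def write_predictions_tsv(records: list[PredictionRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "rank\tgene_id\tassigned_input_gene\tscl_score\tgain_node\t"
            "n_shared_losses\tn_unshared_losses\n"
        )
        for r in records:
            fh.write(
                f"{r.rank}\t{r.gene_id}\t{r.assigned_input_gene}\t{r.scl_value}\t"
                f"{r.gain_node}\t{r.n_shared_losses}\t{r.n_unshared_losses}\n"
            )
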