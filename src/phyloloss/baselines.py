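"""Distance baselines and the leave-half-out cross-validation harness.

Baselines score a candidate against the input set by its best pairwise
profile distance/similarity (minimum Hamming fraction, maximum Jaccard
similarity), ignoring the tree.  The CV harness repeatedly halves each
pathway into an input half and a held-out half, runs a scorer with the
input half, and builds sensitivity/specificity curves where positives are
the held-out genes and negatives are all genes outside the full pathway
(held-out genes are never counted as negatives).  Curves are pooled across
pathways by micro-averaging the confusion counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import annotate_genome
from .profile import PhyloProfile
from .tree import SpeciesTree

__all__ = [
    "RocCurve",
    "CvSplit",
    "hamming_min_score",
    "jaccard_max_score",
    "roc_from_scores",
    "roc_auc",
    "leave_half_out_cv",
    "pooled_roc",
    "make_scl_scorer",
    "make_hamming_scorer",
    "make_jaccard_scorer",
]

#: Sentinel for "gene never predicted at any threshold" (below every cutoff).
NEVER_PREDICTED = -np.inf


@dataclass(frozen=True)
class RocCurve:
    """Threshold sweep with confusion counts and the resulting curve.

    ``thresholds`` are in decreasing order; at threshold t a gene is called
    positive iff its score >= t.  Sensitivity = TP/(TP+FN), specificity =
    TN/(TN+FP); ``auc`` is the trapezoidal area of sensitivity against
    (1 - specificity) with the curve anchored at (0,0) and (1,1).
    """

    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    @property
    def sensitivity(self) -> np.ndarray:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> np.ndarray:
        return self.tn / (self.tn + self.fp)

    @property
    def auc(self) -> float:
        return roc_auc(self)


@dataclass(frozen=True)
class CvSplit:
    """One leave-half-out split of one pathway."""

    pathway_id: str
    input_half: tuple[str, ...]
    held_out_half: tuple[str, ...]
    repeat_index: int  # 1-based


def hamming_min_score(profile: PhyloProfile, gene_set, candidate) -> float:
    """Minimum normalized Hamming distance from the candidate to any input
    gene (fraction of disagreeing species; lower = more similar)."""
    cand = np.asarray(profile.row(candidate) if isinstance(candidate, str) else candidate)
    best = np.inf
    for g in gene_set:
        row = profile.row(g)
        if row.shape != cand.shape:
            raise ValueError("row length mismatch")
        d = np.count_nonzero(row != cand) / row.size
        best = min(best, d)
    return float(best)


def jaccard_max_score(profile: PhyloProfile, gene_set, candidate) -> float:
    """Maximum Jaccard similarity of presence sets between the candidate
    and any input gene (two all-zero rows count as identical: 1)."""
    cand = np.asarray(profile.row(candidate) if isinstance(candidate, str) else candidate)
    best = -np.inf
    for g in gene_set:
        row = profile.row(g)
        if row.shape != cand.shape:
            raise ValueError("row length mismatch")
        union = np.count_nonzero(row | cand)
        if union == 0:
            s = 1.0
        else:
            s = np.count_nonzero(row & cand) / union
        best = max(best, s)
    return float(best)


def roc_from_scores(scores, labels) -> RocCurve:
    """Build a full-sweep ROC from per-gene scores and binary labels.

    Thresholds are the distinct finite scores in decreasing order; genes at
    ``-inf`` (never predicted) stay negative at every threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    if labels.all() or not labels.any():
        raise ValueError("need both positive and negative labels")
    pos = int(labels.sum())
    neg = int(labels.size - pos)
    finite = np.isfinite(scores)
    if not finite.any():
        # degenerate: nothing is ever predicted at any threshold
        return RocCurve(
            thresholds=np.array([0.0]),
            tp=np.array([0]),
            fp=np.array([0]),
            tn=np.array([neg]),
            fn=np.array([pos]),
        )
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    lab = labels[order]
    cum_tp = np.cumsum(lab)
    cum_fp = np.cumsum(~lab)
    # last index of each distinct finite score = counts for "score >= t"
    keep = np.isfinite(s)
    last = np.nonzero(keep & np.r_[s[:-1] != s[1:], True])[0]
    thresholds = s[last]
    tp = cum_tp[last]
    fp = cum_fp[last]
    return RocCurve(thresholds=thresholds, tp=tp, fp=fp, tn=neg - fp, fn=pos - tp)


def roc_auc(curve: RocCurve) -> float:
    """Trapezoidal AUC over (1 - specificity, sensitivity), with the
    endpoints (0, 0) and (1, 1) appended."""
    if curve.thresholds.size < 1:
        raise ValueError("empty curve")
    x = np.concatenate([[0.0], 1.0 - curve.specificity, [1.0]])
    y = np.concatenate([[0.0], curve.sensitivity, [1.0]])
    order = np.argsort(x, kind="stable")
    if x.size < 2:
        raise ValueError("need at least 2 curve points")
    return float(np.trapezoid(y[order], x[order]))


# -- scorers -----------------------------------------------------------------
#
# A scorer is a callable (input_gene_ids, candidate_gene_ids) -> dict mapping
# each candidate to a float where HIGHER means "more likely a pathway member";
# candidates the method never predicts map to -inf.


def make_scl_scorer(
    tree: SpeciesTree,
    profile: PhyloProfile,
    *,
    mode: str = "same",
    annotations=None,
):
    """Tree-based shared-loss scorer (the package's own method)."""
    from .predict import predict  # local import to avoid a cycle

    if annotations is None:
        annotations = annotate_genome(tree, profile)

    def scorer(input_ids, candidate_ids):
        records = predict(
            tree, profile, input_ids, mode=mode, annotations=annotations
        )
        by_gene = {r.gene_id: float(r.scl_value) for r in records}
        return {g: by_gene.get(g, NEVER_PREDICTED) for g in candidate_ids}

    return scorer


def make_hamming_scorer(profile: PhyloProfile):
    """Negated min-Hamming scorer (so that higher = better everywhere)."""

    def scorer(input_ids, candidate_ids):
        return {
            g: -hamming_min_score(profile, input_ids, g) for g in candidate_ids
        }

    return scorer


def make_jaccard_scorer(profile: PhyloProfile):
    def scorer(input_ids, candidate_ids):
        return {
            g: jaccard_max_score(profile, input_ids, g) for g in candidate_ids
        }

    return scorer


def leave_half_out_cv(
    profile: PhyloProfile,
    pathways: dict,
    scorer,
    *,
    n_repeats: int = 5,
    seed: int = 0,
) -> list[tuple[CvSplit, RocCurve]]:
    """Leave-half-out cross-validation of a scorer over a set of pathways.

    For each pathway and each of ``n_repeats`` seeded random halvings, the
    scorer runs with the input half; sensitivity counts recovered held-out
    genes, specificity counts non-pathway genes correctly absent.  Pathways
    with fewer than 2 resolvable genes are skipped with a warning.
    """
    import logging

    logger = logging.getLogger(__name__)
    rng = np.random.default_rng(seed)
    known = set(profile.gene_ids)
    results: list[tuple[CvSplit, RocCurve]] = []
    for pid in sorted(pathways):
        genes = [g for g in pathways[pid] if g in known]
        if len(genes) < 2:
            logger.warning("pathway %s has <2 resolvable genes; skipped", pid)
            continue
        full = set(genes)
        negatives = [g for g in profile.gene_ids if g not in full]
        for rep in range(1, n_repeats + 1):
            perm = rng.permutation(len(genes))
            half = (len(genes) + 1) // 2
            input_half = tuple(genes[i] for i in sorted(perm[:half]))
            held_out = tuple(genes[i] for i in sorted(perm[half:]))
            split = CvSplit(
                pathway_id=pid,
                input_half=input_half,
                held_out_half=held_out,
                repeat_index=rep,
            )
            candidates = list(held_out) + negatives
            scores = scorer(list(input_half), candidates)
            vals = np.array([scores[g] for g in candidates], dtype=float)
            labels = np.array([g in held_out for g in candidates])
            results.append((split, roc_from_scores(vals, labels)))
    if not results:
        raise ValueError("no pathway had >= 2 resolvable genes")
    return results


def pooled_roc(results: list[tuple[CvSplit, RocCurve]]) -> RocCurve:
    """Micro-average CV curves: confusion counts are summed over all splits
    at each threshold of the union grid."""
    grid = np.unique(np.concatenate([c.thresholds for _, c in results]))[::-1]
    tp = np.zeros(grid.size, dtype=np.int64)
    fp = np.zeros_like(tp)
    tn = np.zeros_like(tp)
    fn = np.zeros_like(tp)
    for _, c in results:
        pos = int(c.tp[0] + c.fn[0])
        neg = int(c.tn[0] + c.fp[0])
        # counts at an off-grid threshold equal those at the next-lower
        # attained threshold (step function of the sweep)
        for i, t in enumerate(grid):
            j = np.searchsorted(-c.thresholds, -t, side="right") - 1
            if j < 0:  # stricter than every attained score: nothing called
                ctp = cfp = 0
            else:
                ctp, cfp = int(c.tp[j]), int(c.fp[j])
            tp[i] += ctp
            fp[i] += cfp
            tn[i] += neg - cfp
            fn[i] += pos - ctp
    return RocCurve(thresholds=grid, tp=tp, fp=fp, tn=tn, fn=fn)


def write_roc_tsv(curve: RocCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write("threshold\tTP\tFP\tTN\tFN\tsensitivity\tspecificity\n")
        sens = curve.sensitivity
        spec = curve.specificity
        for i, t in enumerate(curve.thresholds):
            fh.write(
                f"{t:g}\t{curve.tp[i]}\t{curve.fp[i]}\t{curve.tn[i]}\t{curve.fn[i]}\t"
                f"{sens[i]:.6f}\t{spec[i]:.6f}\n"
            )
        fh.write(f"# AUC\t{curve.auc:.6f}\n")
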