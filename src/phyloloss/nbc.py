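"""Bernoulli naive Bayes pre-classification of genome profiles.

Before scanning the genome, every gene is assigned to one input (query)
gene by maximum posterior probability over its binary profile: each input
gene defines a class trained on its own single profile row, each species
is an independent Bernoulli feature, and Laplace smoothing keeps the
one-sample-per-class probabilities non-degenerate.  With the default
``alpha=1`` and uniform priors, a feature matching its class profile has
probability 2/3 and a mismatch 1/3, so classification provably reduces to
nearest-Hamming-distance assignment with ties broken toward the
lowest-indexed class — the classifier is a cheap partitioner, not a
decision-maker, which is why a simple NB model suffices here.

Input genes with byte-identical profiles are merged into one class (their
posteriors would tie everywhere, and an arbitrary split of their
candidates would be meaningless).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .profile import PhyloProfile

__all__ = ["ClassModel", "train", "classify", "classify_genome", "posteriors"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassModel:
    """Per-class Bernoulli feature model over species columns.

    ``class_members[i]`` lists the input gene IDs merged into class ``i``
    (usually a singleton); ``class_profiles[i]`` is their common profile.
    """

    class_members: tuple[tuple[str, ...], ...]
    class_profiles: np.ndarray  # uint8, (n_classes, n_species)
    feature_log1: np.ndarray  # log P(x_j=1 | C_i)
    feature_log0: np.ndarray  # log P(x_j=0 | C_i)
    class_logprior: np.ndarray
    alpha: float

    @property
    def n_classes(self) -> int:
        return len(self.class_members)

    @property
    def n_features(self) -> int:
        return self.class_profiles.shape[1]

    def representative(self, class_index: int) -> str:
        """Canonical input gene for a class (first member in input order)."""
        return self.class_members[class_index][0]


def train(input_profiles, gene_ids=None, *, alpha: float = 1.0) -> ClassModel:
    """Fit one NB class per distinct input-gene profile.

    Parameters
    ----------
    input_profiles : array-like, shape (n_input_genes, n_species)
        One binary row per input gene.
    gene_ids : sequence of str, optional
        IDs for the rows; defaults to ``g0..g{k-1}``.
    alpha : float
        Laplace pseudocount; must be > 0 (with a single training row per
        class, ``alpha=0`` gives 0/1 probabilities and minus-infinity
        posteriors for any mismatch).
    """
    rows = np.asarray(input_profiles, dtype=np.uint8)
    if rows.ndim != 2 or rows.shape[1] == 0:
        raise ValueError("input profiles must be a non-empty 2-D binary matrix")
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(rows.shape[0])]
    gene_ids = [str(g) for g in gene_ids]
    if len(gene_ids) != rows.shape[0]:
        raise ValueError("gene_ids length does not match number of rows")
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate input gene IDs")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")

    # merge identical profiles into one class, preserving first-seen order
    seen: dict[bytes, int] = {}
    members: list[list[str]] = []
    profiles: list[np.ndarray] = []
    for g, row in zip(gene_ids, rows):
        key = row.tobytes()
        if key in seen:
            members[seen[key]].append(g)
        else:
            seen[key] = len(members)
            members.append([g])
            profiles.append(row)
    if len(members) < len(gene_ids):
        merged = [m for m in members if len(m) > 1]
        logger.warning("merged input genes with identical profiles: %s", merged)

    mat = np.stack(profiles)
    # one training sample per class: P(x=1|C) = (x + alpha) / (1 + 2*alpha)
    p1 = (mat + alpha) / (1.0 + 2.0 * alpha)
    return ClassModel(
        class_members=tuple(tuple(m) for m in members),
        class_profiles=mat,
        feature_log1=np.log(p1),
        feature_log0=np.log1p(-p1),
        class_logprior=np.full(len(members), -np.log(len(members))),
        alpha=float(alpha),
    )


def _joint_log_likelihood(model: ClassModel, rows: np.ndarray) -> np.ndarray:
    if rows.ndim == 1:
        rows = rows[None, :]
    if rows.shape[1] != model.n_features:
        raise ValueError(
            f"candidate has {rows.shape[1]} features, model expects {model.n_features}"
        )
    # With one training row per class every feature shares the same two
    # probabilities (match vs mismatch), so the log-likelihood is an affine
    # function of the integer match count.  Counting matches in int64 keeps
    # equal-Hamming ties *exactly* tied, so argmax's first-index rule is the
    # documented lowest-class-index tie-break rather than float noise.
    x = rows.astype(np.int64)
    p = model.class_profiles.astype(np.int64)
    matches = x @ p.T + (1 - x) @ (1 - p).T
    n = model.n_features
    a = model.alpha
    log_match = np.log((1.0 + a) / (1.0 + 2.0 * a))
    log_mismatch = np.log(a / (1.0 + 2.0 * a))
    return (
        model.class_logprior[None, :]
        + matches * log_match
        + (n - matches) * log_mismatch
    )


def classify(model: ClassModel, candidate_row) -> int:
    """Maximum-posterior class for one profile row; ties -> lowest index."""
    jll = _joint_log_likelihood(model, np.asarray(candidate_row, dtype=np.uint8))
    return int(np.argmax(jll[0]))


def posteriors(model: ClassModel, candidate_row) -> np.ndarray:
    """Normalized posterior P(C_i | x) per class (sums to 1)."""
    jll = _joint_log_likelihood(model, np.asarray(candidate_row, dtype=np.uint8))[0]
    w = np.exp(jll - jll.max())
    return w / w.sum()


def classify_genome(model: ClassModel, profile: PhyloProfile) -> dict[str, int]:
    """Assign every profile gene (input genes included) to one class."""
    jll = _joint_log_likelihood(model, profile.values)
    assignment = np.argmax(jll, axis=1)
    return {g: int(c) for g, c in zip(profile.gene_ids, assignment)}
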