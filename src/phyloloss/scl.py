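"""The shared single-and-continuous-loss (SCL) co-evolution score.

Two genes that were gained at the same ancestor and then lost on the same
branches of the species tree are strong candidates for shared function.
The SCL score counts, over the *reference* gene's loss branches, how many
the candidate shares (+1 each) and how many it lacks (-1 each):

    SCL(ref, cand) = |L(ref) & L(cand)| - |L(ref) \\ L(cand)|

where L(g) is gene g's set of loss branches (single or continuous) and
branches are matched by exact tree-edge identity.  The score is asymmetric
by design: losses private to the candidate are not penalized, because the
sum runs over the reference's branches only.  Bounds: -|L(ref)| <= SCL <=
|L(ref)|, attained at disjoint and superset loss sets.
"""

from __future__ import annotations

from dataclasses import dataclass

from .events import GainLossAnnotation

__all__ = ["SclScore", "scl"]


@dataclass(frozen=True)
class SclScore:
    """SCL score decomposition: value = shared - unshared."""

    value: int
    shared: int
    unshared: int


def scl(
    ref: GainLossAnnotation,
    cand: GainLossAnnotation,
    *,
    symmetric: bool = False,
) -> SclScore:
    """Score a candidate gene's loss history against a reference gene's.

    Both annotations must come from the same species tree (edge IDs are
    only comparable on one coordinate system).  With ``symmetric=True`` the
    lower of the two orientations is returned instead of the default
    reference-oriented score.
    """
    if ref.tree is not cand.tree:
        raise ValueError("annotations come from different trees")
    if symmetric:
        a = scl(ref, cand)
        b = scl(cand, ref)
        return a if a.value <= b.value else b
    ref_losses = ref.loss_children
    cand_losses = cand.loss_children
    shared = len(ref_losses & cand_losses)
    unshared = len(ref_losses - cand_losses)
    return SclScore(value=shared - unshared, shared=shared, unshared=unshared)
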