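"""Horizontal-gene-transfer screening of phylogenetic profiles.

Dollo reconstruction is sensitive to spurious presences: a single hit in a
species whose close relatives all lack the gene pulls the gain node toward
the root and inflates the loss count.  The screen flags *isolated
presences* — a gene present in exactly one species of a taxonomic
supergroup (e.g. Animals/Plants/Fungi/Protists) while present somewhere
outside that group — as suspected horizontal transfers.  Two remedies are
offered, mirroring the tool's ``-rv``/``-rm`` switches: revise the flagged
cells to absence, or drop the flagged genes entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .profile import PhyloProfile

__all__ = [
    "HgtDetection",
    "detect_isolated_presence",
    "revise_profile",
    "remove_hgt_genes",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HgtDetection:
    """One suspected HGT presence: gene x species, with its supergroup."""

    gene_id: str
    species_id: str
    group: str


def detect_isolated_presence(
    profile: PhyloProfile,
    groups: dict,
    *,
    require_outside_presence: bool = True,
    min_group_size: int = 2,
) -> list[HgtDetection]:
    """Flag isolated presences per supergroup.

    A detection (gene, species) requires: the gene is present in that
    species, absent in every other member of the species' group, and — by
    default — present in at least one species of some *other* group (a
    gene found in exactly one species anywhere is lineage-specific, not a
    transfer candidate).  Groups smaller than ``min_group_size`` carry no
    "close relatives" signal and are skipped.  A gene may be flagged in
    several groups.
    """
    unmapped = [s for s in profile.species_ids if s not in groups]
    if unmapped:
        raise ValueError(f"species without supergroup assignment: {unmapped}")
    labels = [groups[s] for s in profile.species_ids]
    group_names = sorted(set(labels))
    if len(group_names) < 2 and require_outside_presence:
        raise ValueError("need >= 2 supergroups for HGT detection")
    masks = {g: np.array([l == g for l in labels]) for g in group_names}
    detections: list[HgtDetection] = []
    totals = profile.values.sum(axis=1)
    for gname in group_names:
        mask = masks[gname]
        size = int(mask.sum())
        if size < min_group_size:
            logger.warning("supergroup %s has %d species; skipped", gname, size)
            continue
        in_group = profile.values[:, mask].sum(axis=1)
        isolated = in_group == 1
        if require_outside_presence:
            isolated &= (totals - in_group) >= 1
        species_in_group = [s for s, m in zip(profile.species_ids, mask) if m]
        for gi in np.nonzero(isolated)[0]:
            row = profile.values[gi, mask]
            sp = species_in_group[int(np.nonzero(row)[0][0])]
            detections.append(
                HgtDetection(gene_id=profile.gene_ids[gi], species_id=sp, group=gname)
            )
    detections.sort(key=lambda d: (d.gene_id, d.group, d.species_id))
    return detections


def revise_profile(
    profile: PhyloProfile, detections: list[HgtDetection]
) -> PhyloProfile:
    """Set every detected cell to absence (the ``-rv`` remedy).

    Single-pass: the revised profile is returned as-is; callers wanting a
    fixed point re-detect and revise until no detection remains.  Genes
    driven all-zero are flagged in the log.
    """
    values = profile.values.copy()
    for d in detections:
        gi = profile.gene_index(d.gene_id)
        si = profile.species_ids.index(d.species_id)
        if values[gi, si] != 1:
            raise ValueError(
                f"stale detection: ({d.gene_id}, {d.species_id}) is not a presence"
            )
        values[gi, si] = 0
    revised = PhyloProfile(profile.gene_ids, profile.species_ids, values)
    zeroed = [g for g in revised.all_zero_genes() if profile.row(g).any()]
    if zeroed:
        logger.warning("revision drove %d gene(s) all-zero: %s", len(zeroed), zeroed[:10])
    return revised


def remove_hgt_genes(
    profile: PhyloProfile, detections: list[HgtDetection]
) -> PhyloProfile:
    """Drop every flagged gene's row entirely (the ``-rm`` remedy)."""
    flagged = {d.gene_id for d in detections}
    keep = [i for i, g in enumerate(profile.gene_ids) if g not in flagged]
    return PhyloProfile(
        gene_ids=tuple(profile.gene_ids[i] for i in keep),
        species_ids=profile.species_ids,
        values=profile.values[keep],
    )


def write_detections_tsv(detections: list[HgtDetection], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tspecies\tgroup\n")
        for d in detections:
            fh.write(f"{d.gene_id}\t{d.species_id}\t{d.group}\n")
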