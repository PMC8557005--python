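"""Binary phylogenetic profiles and the flat-file formats around them.

A profile is a genes x species 0/1 matrix: ``1`` means a homolog of the
gene was detected in that species (e.g. a BLASTP hit below an E-value
threshold), ``0`` means none was.  Columns must be aligned to the species
tree's canonical leaf order before any event mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree import SpeciesTree, TreeError, prune_tree

__all__ = [
    "PhyloProfile",
    "ProfileFormatError",
    "AlignmentError",
    "read_profile",
    "write_profile",
    "align",
    "build_profile_from_blast",
    "prune",
    "read_gene_set",
    "read_pathways",
    "read_supergroups",
    "resolve_gene_set",
]

logger = logging.getLogger(__name__)


class ProfileFormatError(ValueError):
    """Malformed profile input (non-binary cells, duplicate IDs, ...)."""


class AlignmentError(ValueError):
    """Profile species and tree leaves do not match."""


@dataclass(frozen=True)
class PhyloProfile:
    """Binary genes x species presence/absence matrix."""

    gene_ids: tuple[str, ...]
    species_ids: tuple[str, ...]
    values: np.ndarray  # uint8, shape (n_genes, n_species)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.uint8)
        if vals.shape != (len(self.gene_ids), len(self.species_ids)):
            raise ProfileFormatError(
                f"matrix shape {vals.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.species_ids)} species"
            )
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ProfileFormatError("profile cells must be 0 or 1")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ProfileFormatError("duplicate gene IDs")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ProfileFormatError("duplicate species IDs")
        object.__setattr__(self, "values", vals)
        vals.setflags(write=False)

    # -- access ----------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def gene_index(self, gene_id: str) -> int:
        idx = getattr(self, "_gidx", None)
        if idx is None:
            idx = {g: i for i, g in enumerate(self.gene_ids)}
            object.__setattr__(self, "_gidx", idx)
        try:
            return idx[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene {gene_id!r}") from None

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_index(gene_id)]

    def all_zero_genes(self) -> list[str]:
        mask = self.values.sum(axis=1) == 0
        return [g for g, z in zip(self.gene_ids, mask) if z]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.gene_ids), columns=list(self.species_ids)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PhyloProfile":
        arr = df.to_numpy()
        bad = ~np.isin(arr, (0, 1))
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise ProfileFormatError(
                f"non-binary value at ({df.index[g]}, {df.columns[s]}): {arr[g, s]!r}"
            )
        return cls(
            gene_ids=tuple(str(g) for g in df.index),
            species_ids=tuple(str(s) for s in df.columns),
            values=arr.astype(np.uint8),
        )


def read_profile(path) -> PhyloProfile:
    """Read a TSV profile: header = species names, first column = gene IDs."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ProfileFormatError(f"{path}: no header") from None
    if df.shape[1] == 0:
        raise ProfileFormatError(f"{path}: no species columns")
    cells = df.to_numpy()
    ok = np.isin(cells, ("0", "1"))
    if not ok.all():
        g, s = np.argwhere(~ok)[0]
        raise ProfileFormatError(
            f"non-binary value at ({df.index[g]}, {df.columns[s]}): {cells[g, s]!r}"
        )
    return PhyloProfile.from_dataframe(df.astype(np.uint8))


def write_profile(profile: PhyloProfile, path) -> None:
    profile.to_dataframe().to_csv(path, sep="\t", index_label="gene")


def align(tree: SpeciesTree, profile: PhyloProfile) -> PhyloProfile:
    """Reorder profile columns to the tree's canonical leaf order.

    Idempotent; raises :class:`AlignmentError` listing offending species if
    the two taxon sets differ.
    """
    leaves = tree.leaf_names
    have = set(profile.species_ids)
    want = set(leaves)
    if have != want:
        msgs = []
        if want - have:
            msgs.append(f"in tree but not profile: {sorted(want - have)}")
        if have - want:
            msgs.append(f"in profile but not tree: {sorted(have - want)}")
        raise AlignmentError("species mismatch; " + "; ".join(msgs))
    if list(profile.species_ids) == leaves:
        return profile
    order = [profile.species_ids.index(s) for s in leaves]
    return PhyloProfile(
        gene_ids=profile.gene_ids,
        species_ids=tuple(leaves),
        values=profile.values[:, order],
    )


def is_aligned(tree: SpeciesTree, profile: PhyloProfile) -> bool:
    return list(profile.species_ids) == tree.leaf_names


def build_profile_from_blast(
    hits,
    evalue_threshold: float,
    gene_ids,
    species_ids,
    *,
    ignore_unknown: bool = False,
) -> PhyloProfile:
    """Build a presence/absence matrix from BLASTP-style tabular hits.

    ``hits`` is an iterable of ``(query_gene, subject_species, evalue)``
    records.  A cell is 1 iff some hit falls strictly below the E-value
    threshold (the conventional ``E-value < 0.001`` homology call); genes
    with no qualifying hit get all-zero rows, which are logged because the
    gain/loss model cannot annotate them.
    """
    if evalue_threshold <= 0:
        raise ValueError("evalue_threshold must be positive")
    gene_ids = [str(g) for g in gene_ids]
    species_ids = [str(s) for s in species_ids]
    gidx = {g: i for i, g in enumerate(gene_ids)}
    sidx = {s: i for i, s in enumerate(species_ids)}
    values = np.zeros((len(gene_ids), len(species_ids)), dtype=np.uint8)
    for rec in hits:
        gene, species, evalue = rec[0], rec[1], float(rec[2])
        if str(species) not in sidx:
            if ignore_unknown:
                continue
            raise ProfileFormatError(f"hit references unknown species {species!r}")
        if str(gene) not in gidx:
            if ignore_unknown:
                continue
            raise ProfileFormatError(f"hit references unknown gene {gene!r}")
        if evalue < evalue_threshold:  # strict inequality
            values[gidx[str(gene)], sidx[str(species)]] = 1
    profile = PhyloProfile(tuple(gene_ids), tuple(species_ids), values)
    zero = profile.all_zero_genes()
    if zero:
        logger.warning("%d gene(s) with no qualifying hit: %s", len(zero), zero[:10])
    return profile


def read_blast_tab(path, *, query_col: int = 0, species_col: int = 1, evalue_col: int = 2):
    """Yield (query, species, evalue) from a tab-separated BLAST hits file."""
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            yield parts[query_col], parts[species_col], float(parts[evalue_col])


def prune(
    tree: SpeciesTree, profile: PhyloProfile, keep_species
) -> tuple[SpeciesTree, PhyloProfile]:
    """Restrict tree and profile to a species subset (taxon subsampling)."""
    keep = [str(s) for s in keep_species]
    extra = set(keep) - set(tree.leaf_names)
    if extra:
        raise TreeError(f"keep_species not in tree: {sorted(extra)}")
    sub_tree = prune_tree(tree, keep)
    missing = set(keep) - set(profile.species_ids)
    if missing:
        raise AlignmentError(f"keep_species not in profile: {sorted(missing)}")
    cols = [profile.species_ids.index(s) for s in sub_tree.leaf_names]
    sub_profile = PhyloProfile(
        gene_ids=profile.gene_ids,
        species_ids=tuple(sub_tree.leaf_names),
        values=profile.values[:, cols],
    )
    return sub_tree, sub_profile


# -- auxiliary flat files ----------------------------------------------------

def read_gene_set(path) -> list[str]:
    """Read a gene-ID list: one ID per line, '#' starts a comment."""
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.append(line)
    if not genes:
        raise ProfileFormatError(f"{path}: empty gene set")
    return list(dict.fromkeys(genes))


def read_pathways(path) -> dict[str, list[str]]:
    """Read a pathway table (``pathway_id<TAB>gene_id`` per line)."""
    pathways: dict[str, list[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ProfileFormatError(f"{path}:{i + 1}: expected pathway<TAB>gene")
            pathways.setdefault(parts[0], []).append(parts[1])
    if not pathways:
        raise ProfileFormatError(f"{path}: no pathways")
    return pathways


def read_supergroups(path) -> dict[str, str]:
    """Read a species -> supergroup mapping (``species<TAB>group``)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ProfileFormatError(f"{path}:{i + 1}: expected species<TAB>group")
            mapping[parts[0]] = parts[1]
    if not mapping:
        raise ProfileFormatError(f"{path}: empty supergroup map")
    return mapping


def resolve_gene_set(profile: PhyloProfile, gene_ids) -> tuple[list[str], list[str]]:
    """Split a gene set into (resolvable, unresolvable) against the profile.

    Unresolvable members are reported to the caller rather than silently
    dropped.
    """
    known = set(profile.gene_ids)
    resolved = [g for g in gene_ids if g in known]
    missing = [g for g in gene_ids if g not in known]
    if missing:
        logger.warning("gene set members absent from profile: %s", missing)
    return resolved, missing
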