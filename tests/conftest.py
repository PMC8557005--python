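import numpy as np
import pytest

import phyloloss as pl


@pytest.fixture
def toy_tree():
    """The 5-taxon worked example: (((A,B),(C,D)),E).

    Post-order node IDs: A=0, B=1, (A,B)=2, C=3, D=4, (C,D)=5,
    ((A,B),(C,D))=6, E=7, root=8.
    """
    return pl.read_newick("(((A,B),(C,D)),E);")


@pytest.fixture
def toy_profile(toy_tree):
    """Profile with known loss structure on the toy tree.

    g_ref:  present A, E      -> losses {->B single, ->(C,D) continuous}
    g_same: identical to g_ref
    g_sub:  present A, C, D, E -> loss {->B single}
    g_all:  present everywhere -> no losses
    g_off:  present C, D only  -> gain at (C,D), no losses
    """
    rows = {
        "g_ref": [1, 0, 0, 0, 1],
        "g_same": [1, 0, 0, 0, 1],
        "g_sub": [1, 0, 1, 1, 1],
        "g_all": [1, 1, 1, 1, 1],
        "g_off": [0, 0, 1, 1, 0],
    }
    return pl.PhyloProfile(
        gene_ids=tuple(rows),
        species_ids=tuple(toy_tree.leaf_names),
        values=np.array(list(rows.values()), dtype=np.uint8),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_profile_rows(n_rows, n_leaves, rng, min_presence=1):
    """Random binary rows, each with at least ``min_presence`` ones."""
    rows = rng.integers(0, 2, size=(n_rows, n_leaves)).astype(np.uint8)
    for i in range(n_rows):
        while rows[i].sum() < min_presence:
            rows[i] = rng.integers(0, 2, size=n_leaves)
    return rows
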