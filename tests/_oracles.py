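"""Independent reference implementations used only to check the package.

These deliberately avoid the library's linear-scan code paths:

* ``brute_force_dollo`` enumerates every internal-state assignment with a
  single gain origin and returns the minimum-loss one (asserting it is
  unique) — feasible for small trees only.
* ``set_dollo`` reconstructs by literal leaf-set arithmetic (subset tests
  and intersections), usable at moderate size.
* ``literal_scl`` evaluates the shared-loss score by summing the
  (ancestral - descendant) state differences branch by branch, instead of
  counting set sizes.
* ``posterior_classify`` computes naive-Bayes posteriors feature by
  feature in plain Python floats.
"""

from itertools import product

import numpy as np


def brute_force_dollo(tree, row):
    """Exhaustive minimal-change Dollo reconstruction.

    Enumerates all 0/1 assignments to internal nodes (leaves fixed by the
    profile row), keeps those with exactly one gain origin (a 0->1 edge,
    or state 1 at the root), and returns the unique assignment minimizing
    the number of 1->0 edges.
    """
    n = tree.n_nodes
    internal = [v for v in range(n) if tree.children[v]]
    leaf_ids = list(tree.leaf_ids)
    assert len(row) == len(leaf_ids)
    states = [0] * n
    for l, v in zip(leaf_ids, row):
        states[l] = int(v)
    if sum(states[l] for l in leaf_ids) == 0:
        raise ValueError("all-zero row")
    best = None
    best_losses = None
    ties = 0
    for bits in product((0, 1), repeat=len(internal)):
        for v, b in zip(internal, bits):
            states[v] = b
        origins = []
        losses = []
        if states[tree.root] == 1:
            origins.append(tree.root)
        for child in range(n - 1):
            p = int(tree.parent[child])
            if states[p] == 0 and states[child] == 1:
                origins.append(child)
            elif states[p] == 1 and states[child] == 0:
                losses.append(child)
        if len(origins) != 1:
            continue
        if best is None or len(losses) < len(best_losses):
            best = (origins[0], tuple(states), sorted(losses))
            best_losses = losses
            ties = 1
        elif len(losses) == len(best_losses):
            ties += 1
    assert best is not None, "no feasible single-gain assignment"
    assert ties == 1, "minimal Dollo reconstruction is not unique on this input"
    gain, st, losses = best
    return gain, np.array(st, dtype=np.uint8), losses


def set_dollo(tree, row):
    """Leaf-set-arithmetic Dollo reconstruction (no counting pass).

    gain = smallest-clade node whose leaf set contains every presence
    leaf; a node is present iff its clade intersects the presence set;
    losses are the absent children of present nodes inside the gain clade.
    """
    leaf_ids = list(tree.leaf_ids)
    present = {l for l, v in zip(leaf_ids, row) if v}
    if not present:
        raise ValueError("all-zero row")
    clades = {v: set(tree.clade_leaves(v)) for v in range(tree.n_nodes)}
    covering = [v for v in range(tree.n_nodes) if clades[v] >= present]
    gain = min(covering, key=lambda v: len(clades[v]))
    in_clade = {v for v in range(tree.n_nodes) if clades[v] <= clades[gain]}
    states = np.zeros(tree.n_nodes, dtype=np.uint8)
    for v in in_clade:
        if clades[v] & present:
            states[v] = 1
    losses = [
        v
        for v in sorted(in_clade - {gain})
        if states[int(tree.parent[v])] == 1 and states[v] == 0
    ]
    return gain, states, losses


def literal_scl(ref_ann, cand_ann):
    """Shared-loss score by literal branch-wise summation of
    (ancestral state - descendant state) over the reference's loss
    branches, split by whether the candidate shares the branch."""
    cand_edges = {(b.parent_id, b.child_id) for b in cand_ann.losses}
    shared_sum = 0
    unshared_sum = 0
    for b in ref_ann.losses:
        anc = int(ref_ann.states[b.parent_id])
        desc = int(ref_ann.states[b.child_id])
        term = anc - desc
        if (b.parent_id, b.child_id) in cand_edges:
            shared_sum += term
        else:
            unshared_sum += term
    return shared_sum - unshared_sum


def posterior_classify(class_profiles, candidate, alpha=1.0):
    """Plain-float naive-Bayes posterior argmax (lowest index on ties)."""
    from fractions import Fraction

    best_i = 0
    best_p = None
    for i, prof in enumerate(class_profiles):
        p = Fraction(1)
        for x, c in zip(candidate, prof):
            p1 = Fraction(int(c) + 1, 3) if alpha == 1.0 else None
            assert p1 is not None, "oracle only supports alpha=1"
            p *= p1 if x else (1 - p1)
        if best_p is None or p > best_p:
            best_p = p
            best_i = i
    return best_i


def nearest_hamming(class_profiles, candidate):
    """argmin Hamming distance, lowest index on ties."""
    dists = [int(np.count_nonzero(np.asarray(p) != np.asarray(candidate)))
             for p in class_profiles]
    return int(np.argmin(dists))
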