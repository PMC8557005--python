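# Methods

## Model

Every gene is modelled as a binary character on a rooted species tree
evolving under Dollo parsimony: one gain, any number of subsequent losses.
Branch lengths are ignored everywhere — only topology carries signal.
Under the single-gain constraint the minimal-change ancestral
reconstruction is unique and closed-form:

* **gain node** — the LCA of the presence leaves (the leaf itself for a
  species-specific gene);
* **states** — 0 outside the gain clade ("never gained"), and inside it
  1 exactly where ≥ 1 presence leaf descends;
* **loss branches** — edges with a 1→0 transition. They are maximal by
  construction (a loss edge's parent always has a surviving presence
  descendant), and are classed *single* when the lost clade is one leaf
  and *continuous* when it spans ≥ 2 leaves. The class is purely a
  function of the child node's leafness; this is recorded as the
  operational definition since single-vs-continuous is otherwise
  informal.

The implementation computes all three in one bottom-up counting pass plus
one pass over the gain clade; each annotation carries an instrumented
`node_visits` counter, which the tests use to verify that per-gene work
stays ≤ 2 · (node count) from 64 to 512 leaves.

Trees are stored with deterministic post-order node IDs (children in file
order), so a node's subtree is the contiguous ID interval
`[first_desc[v], v]`; ancestor tests and clade extraction are O(1)/O(k)
and every event report is byte-reproducible across runs. Polytomies are
accepted on input (each child edge of a polytomous node is an independent
loss candidate); strictly bifurcating trees are not enforced.

## SCL score

`SCL(ref, cand) = |L(ref) ∩ L(cand)| − |L(ref) \ L(cand)|`, with loss
branches matched by exact tree-edge identity. Numerical choices:

* **Orientation** — the reference is the input (query) gene; candidate-only
  losses contribute nothing, because the defining sums run over the
  reference's branches only. A symmetric variant (the lower of the two
  orientations) exists behind `symmetric=True` but is off by default.
* **Matching granularity** — exact edges. A candidate that loses a
  sub-clade of the reference's lost clade does *not* get partial credit:
  the branch counts as unmatched (−1). No principled partial-credit rule
  exists for set-valued events; exact matching is the literal reading of
  the definition.

## Naive Bayes pre-classification

Each input gene defines one class trained on its single profile row;
species are independent Bernoulli features with Laplace smoothing
(`alpha=1` default — with one sample per class, `alpha=0` degenerates to
0/1 probabilities) and uniform class priors (a single training row per
class carries no empirical prior). Log-space throughout. With these
defaults the posterior argmax is provably the nearest input gene by
Hamming distance, ties to the lowest class index; the implementation
computes log-likelihoods from exact integer match counts so that ties are
exact rather than float-order artifacts. Input genes with identical
profiles are merged into one class (their posteriors tie everywhere; an
arbitrary split of their candidates would be meaningless) with the first
member as the class representative.

## Prediction pipeline

annotate → classify → gain-node filter → SCL → rank. Defaults: search
mode `same`; each candidate scored only against its assigned input gene
(`aggregate="max"` scores against all input genes for sensitivity
analysis); input genes excluded from the output; ties in score ordered by
gene ID so ranks are reproducible; no score threshold unless requested.
The search modes are inclusive: a candidate gained at the same node as
the reference passes every mode, `earlier`/`later` additionally admit
strict ancestors/descendants, and `both` admits any of the three. (An
exclusive reading of `earlier`/`later` would reject candidates whose gain
coincides with the query's — the genes the method most wants.) Worker
threads parallelize the per-candidate scans; the merge is a deterministic
sort, so output is independent of thread count.

## Baselines and cross-validation

Hamming: minimum over input genes of the fraction of disagreeing species
(reported normalized; the min-ranking is invariant to normalization).
Jaccard: maximum presence-set similarity; two all-zero rows count as
identical (similarity 1). Leave-half-out CV: each pathway is randomly
halved `n_repeats` times (seeded); the scorer runs with the input half;
sensitivity counts held-out genes recovered at each score threshold,
specificity counts non-pathway genes correctly absent. The negative
universe excludes the full pathway, so held-out genes are never counted
as negatives. Genes a method never predicts (e.g. filtered out by the
gain-node test) stay negative at every threshold. Curves are pooled
across pathways by micro-averaging confusion counts on the union
threshold grid (macro-averaging per-split AUCs is available by averaging
`RocCurve.auc` values directly); AUC is the trapezoidal area of
sensitivity against 1 − specificity anchored at (0,0) and (1,1).

## HGT screen

An *isolated presence* — a gene present in exactly one species of a
supergroup, absent in all of that species' group relatives, and present
somewhere outside the group — is flagged as a suspected horizontal
transfer. The outside-presence condition is deliberate: without it every
lineage-specific gene would be flagged; it can be disabled
(`require_outside_presence=False`). Groups smaller than `min_group_size`
(default 2) carry no "close relatives" signal and are skipped. Remedies:
revise flagged cells to absence (`rv`) or drop flagged genes (`rm`).
Revision is single-pass by default, matching a one-shot profile cleanup;
iterating detection+revision reaches a fixed point in at most one pass
per group. Supergroup maps are user-supplied TSV (species → group); a
typical eukaryote panel uses Animals/Plants/Fungi/Protists at roughly
phylum level.

## Profile construction and pruning

BLASTP tabular hits become presences via a strict threshold (`E-value <
0.001` by default; a hit exactly at the threshold is absence). All-zero
rows are kept in the matrix but skipped (with a warning) by annotation
and prediction — the Dollo model needs at least one presence. Pruning to
a species subset suppresses unary internal nodes and renumbers
post-order; it is the mechanism for taxon-subsampling experiments.
Copy-number (non-binary) profiles are out of scope: the loss model is
defined on presence/absence only.

## Synthetic data

`simulate_study` emulates the study conditions the method targets:

| parameter | default | meaning |
|---|---|---|
| `n_species` | 64 | leaves of a random coalescent-style bifurcating tree |
| `n_background_genes` | 2000 | genes with independent random gain nodes; each edge inside the gain clade lost with `loss_prob` |
| `pathway_sizes` | (20,) | gene sets sharing one gain node and a common loss core |
| `loss_prob` | 0.1 | per-edge loss probability for background genes |
| `shared_loss_branches` | 3 | disjoint loss edges common to all pathway members |
| `jitter_branches` | 1 | max extra private losses per pathway member |
| `flip_noise` | 0.01 | per-cell flip probability, applied last (models homology-calling errors) |

Recorded truth is always the *canonical* Dollo form implied by the leaf
pattern (losses are merged to maximal edges and restricted to the LCA
clade of the survivors), because that is the only representation any
reconstruction can observe; the pathway core and jitter draws are
rejected if they would perturb the canonical form. All-zero rows are
resampled (bounded retries). Everything is bit-reproducible per seed.

What the generator does **not** emulate: correlated noise (real homology
errors cluster by genome quality), rate heterogeneity across lineages,
convergent loss patterns between unrelated pathways, and backgrounds that
mimic a pathway's bit pattern without sharing its events. Passing
recovery tests therefore show internal consistency at realistic sizes,
not performance on real proteomes. Notably, with near-identical pathway
rows and i.i.d. backgrounds the plain Hamming/Jaccard baselines operate
at their ceiling, and i.i.d. flip noise shifts inferred gain nodes (one
spurious presence outside the clade moves the LCA rootward), which the
strict `same` filter punishes; the `both` mode and the HGT `rv` screen
are the built-in mitigations.

## Problem sizes used in the checked results

The test suite and `scripts/acceptance.py` use: exhaustive profiles on
all ≤ 8-leaf example trees plus 10⁴ random 16-leaf cases for the Dollo
oracle; 10⁴ random pairs/candidates for the SCL and classifier checks;
50 six-gene pathways for the null-CV calibration; 20 study seeds at the
default conditions above with 3 CV repeats per seed for recovery; and
64–512-leaf trees for the work-scaling ratio. These sizes are the
package's reference configuration for desk-scale validation.

## Known limitations

* Dollo parsimony assumes rare gains; prokaryote-scale HGT violates it,
  so the method is intended for eukaryote panels.
* The SCL score under-rewards biologically real but non-identical loss
  histories (nested or overlapping lost clades score as mismatches).
* Ancestral reconstruction is deterministic, not probabilistic: no
  uncertainty is attached to events, and a wrong species-tree topology
  propagates directly into wrong events.
* The classifier bucketing means a candidate is only ever compared with
  one input gene (by default); genuinely multi-pattern pathways rely on
  the halving CV or `aggregate="max"` to surface alternatives.
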