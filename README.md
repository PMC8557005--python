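# phyloloss

Tree-based phylogenetic profiling: infer which genome genes co-evolve with
a known pathway or protein complex by *shared gene-loss events* on a
species tree.

## The problem

A phylogenetic profile records, for one gene, the presence (1) or absence
(0) of a homolog in each of a panel of genomes. Genes that work together —
members of one complex or pathway — tend to be gained and lost together
over evolution, so a gene whose profile resembles the profiles of a known
gene set is a candidate member of that set. Plain profile distances
(Hamming, Jaccard) exploit the pattern but ignore *why* two profiles
match: many false positives share the pattern by chance without sharing
any evolutionary event. Mapping profiles onto the species tree and
comparing the inferred **loss events** instead of the raw bit patterns
uses strictly more information at the same asymptotic cost.

## The model

Each gene is assumed to evolve under **Dollo parsimony**: it is gained
exactly once and can only be lost thereafter. Given a rooted species tree
and a gene's binary profile over the leaves:

- the **gain node** is the lowest common ancestor (LCA) of all presence
  leaves;
- inside the gain clade a node's ancestral state is 1 iff at least one
  presence leaf descends from it (0 everywhere outside the clade — the
  gene was never there);
- every edge whose parent has state 1 and child state 0 is a **loss
  branch**: a *single* loss if the child is a leaf (one species lost the
  gene independently), a *continuous* loss if the child is an internal
  node (an entire clade of ≥ 2 species lost it together).

This reconstruction is unique, and one bottom-up pass computes it in O(n)
per gene for n tree nodes.

Candidates are ranked against a reference gene A by the **SCL score**
(shared single-and-continuous-loss score):

```
SCL(A, B) = Σ_{i ∈ L(A) ∩ L(B)} (anc_i − desc_i) − Σ_{i ∈ L(A) \ L(B)} (anc_i − desc_i)
          = |L(A) ∩ L(B)| − |L(A) \ L(B)|
```

where L(g) is gene g's set of loss branches and anc_i = 1, desc_i = 0 on
every loss branch. Each loss branch of A that B shares earns +1, each one
B lacks costs −1, so −|L(A)| ≤ SCL ≤ |L(A)|. The score is deliberately
asymmetric: losses private to the candidate are not penalized.

The full genome scan is: (1) map every gene's profile to gain/loss events;
(2) partition the genome among the input genes with a Bernoulli naive
Bayes classifier (with one training profile per class and Laplace α = 1
this provably reduces to nearest-Hamming assignment — it is a cheap
bucketing step, not a decision-maker); (3) keep candidates whose gain node
matches their assigned input gene's (search modes: `same`, `earlier`,
`later`, `both`); (4) score by SCL and rank.

The package also provides min-Hamming and max-Jaccard baseline scorers, a
leave-half-out cross-validation harness with sensitivity/specificity/ROC
curves, an HGT screen that flags *isolated presences* (a gene present in
exactly one species of a taxonomic supergroup but present elsewhere) and
either revises them to absence (`rv`) or drops the gene (`rm`), profile
construction from BLASTP tabular hits (presence iff E-value < threshold),
tree/profile pruning for taxon subsampling, and a synthetic-data generator
with full gain/loss ground truth.

## Worked example

Five genomes on the tree `(((human,mouse),(yeast,spombe)),athaliana);`,
two query genes (`QRY1`, `QRY2`) present only in human and A. thaliana —
i.e. gained at the root, then one single loss (mouse) and one continuous
loss (the whole yeast clade) — and four genome candidates:

```sh
phyloloss predict --tree tree.nwk --profile profile.tsv \
    --genes genes.txt --out predictions.tsv
```

`predictions.tsv`:

```
rank	gene_id	assigned_input_gene	scl_score	gain_node	n_shared_losses	n_unshared_losses
1	CANDA	QRY1	2	8	2	0
2	CANDB	QRY1	0	8	1	1
3	CANDC	QRY1	-2	8	0	2
```

`CANDA` repeats the query's loss history exactly (+1 for the mouse loss,
+1 for the yeast-clade loss: SCL = 2 = |L(QRY1)|, the maximum). `CANDB`
shares the mouse loss but kept the yeast clade (+1 − 1 = 0). `CANDC` is
present everywhere: same gain node but neither loss (−2, the minimum).
`CANDD` lives only in the yeast clade — a different gain node — so the
default `same` search mode filters it out entirely. Node 8 is the root in
the tree's deterministic post-order numbering. A JSON run summary
(`predictions.tsv.summary.json`) records inputs, counts and version.

Other subcommands: `validate` (cross-validated ROC/AUC for the SCL,
Hamming or Jaccard scorer), `hgt-filter`, `simulate`, `build-profile`.
Everything is also available as a library (`import phyloloss`).

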