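# Methods

## Model and assumptions

The package treats marker discovery as a supervised problem defined *after*
clustering: the expression matrix (genes × cells, any non-negative scale)
and the cluster assignment are inputs, and each cluster is classified
one-vs-all against every other cell. Nothing is normalised or
batch-corrected here — cluster membership is assumed to already be robust,
and thresholds are learned from whatever scale the caller supplies, so the
method is scale-agnostic (linear TPM and log counts both work, with
different learned thresholds).

**Step 1 — instrumented forest ranking.** For a target cluster, a bagged
ensemble of decision trees is grown on bootstrap samples (with replacement,
size = number of cells, drawn from the full positive+negative pool so the
natural class imbalance is preserved). At every node `mtry` genes are drawn
uniformly without replacement; the candidate (gene, threshold) pair
maximising the Quinlan information gain ratio — information gain divided by
the entropy of the left/right partition sizes — is chosen, with thresholds
at midpoints between consecutive distinct observed values. The tree builder
is written in-house because the ranking requires two things mainstream
forest libraries do not expose: gain-ratio splitting and a per-node record
of the sampled candidate set. Each gene is scored as
`usage / candidacy` aggregated jointly over the first three branching
levels (root = level 1) of all trees; the ratio keeps scores in [0, 1] and
a perfectly discriminative gene scores 1 at root-level nodes (at very small
deep nodes a noise gene can tie it by chance). Candidacy is counted once
per node at splitting nodes.

**Step 2 — stepwise constrained trees.** Single decision trees are grown
greedily on the top-k ranked genes for k = 1, 2, …, on all cells with no
subsampling, under the restriction that a gene may occupy at most one
internal node anywhere in the tree (the strictest reading of
one-branch-per-gene; enforced depth-first, so the left subtree consumes
genes before the right). Leaves predict the target cluster iff a strict
majority of their training cells belong to it — ties break to negative, the
conservative direction for marker claims. The tree is scored on the target
cluster only, by F_β on the training data (no holdout: the goal is a
definition of this dataset's cluster, not generalisation error). The
markers are the genes the winning tree actually uses, not the whole prefix,
signed by the branch direction on the paths into positively-predicting
leaves; if positive leaves sit on both sides of a gene's node, the side
covering more positive training cells decides the sign.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `n_trees` | 1000 (200 in the simulation studies) | forest size; more trees stabilise candidacy counts |
| `mtry` | ⌈√n_genes⌉ | candidate genes per node |
| `bootstrap_size` | n_cells | bootstrap draws per tree |
| `max_rank_levels` | 3 | branching levels feeding the ranking |
| `beta` | 1.0 | recall/precision weight of the target-cluster F-measure |
| `epsilon` | 0.01 | minimum score improvement that counts as progress |
| `patience` | 2 | consecutive non-improving prefix growths before stopping |
| `max_genes` | 10 | prefix cap |

"Optimal classification or stable tree topology" is operationalised as:
stop at a perfect score, or when the best score has not improved by more
than ε for `patience` consecutive prefix sizes, or at `max_genes`; return
the smallest prefix attaining the best recorded score. Plain accuracy is
not used anywhere: under one-vs-all imbalance a classifier predicting
"never the target" is ~94% accurate on a 16-cluster dataset, so the
target-cluster F-measure is the score.

## Numerical and design choices

* **Gain-ratio ties** break by gene id (lexicographic), then smaller
  threshold — a total order, so forests, rankings and trees are
  bit-identical across runs given the seed (numpy PCG64 throughout).
* **Ranking order** is score descending, then candidacy descending (more
  evidence first), then gene id.
* **Ranking forests are grown only to depth `max_rank_levels`.** Nodes
  deeper than the counted levels cannot contribute to usage or candidacy,
  and growing pure-noise regions to purity has unbounded cost; the
  standalone forest fitter still defaults to growth-to-purity.
* **Per-cluster seeds** are `base_seed + crc32(label) mod 2³¹`, so adding
  or removing one cluster never perturbs another cluster's result.
* **Degenerate inputs**: constant genes are retained (they can never win a
  split) with an optional drop-constant filter for speed; a cluster whose
  best tree never produces a positively-predicting leaf raises a
  "cluster unresolvable" error carrying the best score reached, and the
  all-clusters driver collects such errors instead of aborting.
* **Absence-only marker sets** (all markers negative) are valid selection
  results but cannot be named — the naming grammar leads with a positively
  expressed gene — so definition building skips them.
* **Definition grammar**: marker lists join as `A and B and C` (`all_and`,
  the dominant printed style) or `A, B and C` (`oxfordless_comma`); the
  positive clause always ends "mRNAs", a single negative marker takes
  singular "mRNA". The packaged 16-cluster reference table stores each
  row's observed style (including two rows whose names use a space instead
  of "-expressing", and one row whose printed definition deviates from the
  productive grammar and is kept verbatim only).

## What the simulator emulates — and what it does not

`simulate_dataset` plants, per cluster, 1–5 marker genes drawn
negative-binomial (the standard overdispersed family for RNA-seq-like
counts) with mean `marker_mu_on` = 50 inside and `marker_mu_off` = 1
outside the owning cluster, dispersion 10, over 500 exchangeable noise
genes; defaults are 16 clusters × 50 cells. A quarter of the clusters are
*conjunctive* — each of their first two markers is shared with a distinct
confounder cluster, so only the two-gene conjunction is specific, imitating
transcriptomically similar neuronal subtypes that need more genes — and a
quarter own a *negative* marker expressed everywhere except the cluster.
These settings give strong but not degenerate separation (on/off mean ratio
50, well above the ≥ 20 regime the recovery property targets).

Deliberately not modelled: dropout/zero-inflation calibrated to real
snRNA-seq, batch effects, library-size variation, cell-cycle structure, or
doublets. Passing the recovery study therefore shows the algorithm
correctly inverts its own generative assumptions — planted markers exist
and are recoverable — not that real tissue will yield marker sets of any
particular size or purity. The label-permutation null shows the stopping
rule does not manufacture perfect marker sets from exchangeable noise.

## Problem sizes used in the studies

The recovery study runs 20 seeds of the default 16 × 50-cell configuration
with 200-tree forests (≈ 6 minutes on one CPU); the null study runs 20
seeds of an 8-cluster × 30-cell, 200-noise-gene configuration with permuted
labels; the oracle comparison uses a 6-gene × 60-cell conjunctive fixture
small enough for exhaustive enumeration of all one-use trees over gene
subsets of size ≤ 3. Forest size 200 (rather than the 1000-tree default)
keeps the studies fast; candidacy counts at 200 trees are already stable
enough for the ranking to be reliable at these gene counts.

## Known limitations

* Greedy stepwise search over ranked prefixes is not exhaustive: a minimal
  set that requires a gene the forest ranks below `max_genes` will be
  missed (the oracle-equivalence test bounds this on small instances only).
* The one-use constraint makes clusters occupying a *middle* band of a
  single gene's range inexpressible with one gene (two thresholds would be
  needed); a second gene must step in.
* A perfect classifier need not use the cluster's "own" genes: excluding a
  confounder via *its* marker's absence can be an equally perfect, smaller
  tree. The recovery metric counts only subsets of the planted signed
  markers as successes, so it understates classification performance.
* Candidacy counting (once per node, splitting nodes only) is one of
  several defensible conventions; scores shift slightly under alternatives,
  though rankings of strongly separating genes are robust to the choice.
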