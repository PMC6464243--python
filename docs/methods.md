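# Methods

This note documents the models implemented in `mirdap`, the defaults and
why they were chosen, the numerical safeguards, what the synthetic
generator does and does not emulate, and the known limitations.

## Disease semantic similarity

Each disease is described by one or more dotted tree numbers (e.g.
`C04.588.180`); truncating trailing segments yields its ancestors, and
the per-disease ancestor graph keys nodes by the disease *name* owning a
tree number (falling back to the tree-number string when no owner
exists), so a disease reachable through several tree numbers is one
node. When a disease owns tree numbers at several depths of the same
chain the name-merged graph acquires a cycle; strongly connected
components are then contracted to a single node, which preserves
acyclicity and the ancestor semantics.

Contributions decay by ε per edge: `D(d) = 1` for the disease itself and
`D(s) = max_{s' ∈ children(s)} ε·D(s')` for an ancestor, evaluated
bottom-up (the max over equal candidates makes tie-breaking irrelevant).
The semantic value `DV(d)` is the sum of contributions, and model 1
scores a pair by the contributions of shared ancestors over the summed
semantic values, which lies in [0, 1] with self-similarity exactly 1.

Model 2 replaces a shared node's contribution with its corpus-level
information content `−log(num(DAGs(s)) / num(diseases))`, so ancestors
shared by few diseases count more. The denominator keeps the model-1
semantic values; consequently model-2 values are *not* bounded by 1 and
self-similarity is generally ≠ 1. They are deliberately not clipped —
the fused disease similarity consumes them as-is.

Defaults: ε = 0.5 (the convention of this similarity-model family;
exposed in `SemanticConfig`) and the natural logarithm for information
content (the base only rescales model 2 by a constant factor;
configurable to 2 or 10).

## Gaussian interaction-profile kernels

A disease's interaction profile is its adjacency row, a miRNA's its
column; similarity is `exp(−θ·‖V_i − V_j‖²)`. The width is
`θ = θ′ / ((1/m)·Σ‖V_i‖²)` with θ′ = 1 — the normalised convention, so
the kernel scale adapts to network density. The literal un-inverted
variant `θ = (1/m)·Σ‖V_i‖²` appears in parts of the literature and is
available as `gip_width(..., literal=True)`. All-zero profile sets
degenerate to θ = 0 (similarity 1 everywhere) with a logged warning;
entities with empty profiles otherwise participate exactly as the
formula dictates.

## Sequence embedding

Sequences are tokenised into overlapping k-mers (k = 6 by default; a
length-l sequence yields l−k+1 tokens). The skip-gram model is trained
by seeded single-threaded SGD with negative sampling (5 noise words from
the unigram^0.75 distribution; a full-softmax objective is available for
small vocabularies), window 5 with per-position uniform shrinkage,
64 dimensions, 10 epochs, min_count 5, linear learning-rate decay from
0.025. Tokens below min_count are removed before windowing, as is usual
for this model family. Determinism: identical seeds give bit-identical
vectors.

Pooling a miRNA's token vectors into one row uses the arithmetic mean —
the standard order-invariant choice that keeps the descriptor width
fixed; a sequence with no in-vocabulary token maps to the zero vector
(with a warning) for the same reason. An optional
variance/principal-component reduction stage exists in
`assemble_dataset(reduce_to=...)` but is off by default: the classifier
consumes the raw fused descriptor.

## Feature fusion and negative sampling

DSim averages the two semantic models when both diseases are
ontology-covered and otherwise uses the disease kernel — the fallback is
used *only* when semantic similarity is unavailable, never averaged with
it. RSim likewise prefers the precomputed functional matrix and falls
back to the miRNA kernel. (The similarity condition is on the two
miRNAs, not diseases.) Every entry carries a provenance flag. The
descriptor concatenates the DSim row, the RSim column and the RSeq row:
width n_diseases + n_mirnas + 64; the `DescSeq` ablation drops the RSim
block and `DescSim` drops the RSeq block.

Negatives are drawn uniformly without replacement from the zero cells of
the adjacency matrix, seeded, and by default balanced 1:1 against the
positives, so the dataset size is always 2·|positives|.

## Logistic model tree

Node models are additive logistic models built by two-class LogitBoost:
probabilities `p = 1/(1+e^{−2F})`, working responses
`z = (y − p)/(p(1−p))` with weights `w = p(1−p)` (weights floored at
1e-10, responses clipped at |z| ≤ 4, probabilities clamped to
[1e-10, 1−1e-10]), and each round adds half of the best one-attribute
weighted least-squares regressor. Because the base learners are linear,
F stays linear and a node model is just (intercept, coefficients).

Numerical safeguard: with clipped responses the half-step Newton update
can *increase* the loss near separation (the clipped pull of
misclassified points no longer balances the push of confident ones; we
observed monotone divergence on a reproducible 80-row example). Each
step is therefore backtracked — halved up to 8 times until the training
negative log-likelihood does not increase — and a step that cannot
improve becomes a terminating no-op, which makes the training loss
provably non-increasing and is the property the test suite asserts.

The boosting round count at every node is chosen by internal stratified
5-fold CV on that node's rows (held-out misclassification per round,
earliest minimum; plateau early-stopping with patience 25). Choosing the
count per node rather than once at the root matters here: when the
signal is a pure interaction, the root-level problem is linearly
unlearnable and root CV picks a handful of rounds, starving every
descendant model.

Splits are axis tests on midpoint thresholds. Candidates — each
attribute's best cut by information gain, plus its best *balanced* cut
(no child under 30 % of rows), excluding cuts that leave a child below
min_instances/3 — are re-ranked by a one-step lookahead: briefly boosted
child models (8 rounds, warm-started) are fitted for the top 8
candidates and the split whose children best explain the labels (lowest
summed deviance) wins. Plain argmax-gain is recoverable with
`lookahead_candidates=1`. The lookahead exists because the class
variable can be marginally independent of every attribute even when one
split makes the node separable; pure information gain is then noise, and
with a hundred-plus attributes its argmax systematically selects
uninformative slivers.

Children warm-start from the parent's F and continue boosting on their
rows only — the defining trick of the model family, not optional. Growth
stops at purity, under 15 rows (min_instances), or depth 5. Pruning is
CART cost-complexity on training misclassification: the critical-alpha
sequence is computed by weakest-link collapsing, candidate alphas are
the geometric midpoints, and the strength is selected by internal 5-fold
CV (fold trees reuse the main tree's iteration count — the alpha
comparison needs comparable structure, not freshly tuned node models);
ties prefer the smaller tree. Models persist to a documented JSON tree.

Baselines: RBF-SVM with C = 0.5 and γ = 0.2, and a random forest of
depth-2 trees, both via scikit-learn behind the same
fit/predict_proba contract.

## Evaluation

Accuracy, sensitivity, precision and MCC come from the confusion matrix
at probability threshold 0.5; a metric whose denominator is zero is
reported as 0 and flagged. AUC is the trapezoidal area under the ROC
curve (identical to the tie-corrected pair-counting statistic, which the
tests verify independently). Cross-validation is stratified (plain
"disjoint and roughly equal" folds destabilise small runs; fold sizes
differ by at most one and each row is tested exactly once) and fully
seeded. Candidate ranking scores all miRNAs for a disease, includes
known positives with a flag by default (so verifiable entries remain
visible), and breaks ties by name. ROC/PR points export as CSV; no
plotting dependency is required.

## Synthetic data: what it emulates and what it shows

The generator produces the four inputs with one shared cluster
structure: a tree-number hierarchy in which cluster members share a
depth-3 ancestor and different clusters only the root; 20–25 nt
sequences, each carrying its cluster's planted 8-mer motif; a block-model
adjacency (within-block rate p_in = 0.6, background p_out = 0.05 over
40 diseases × 60 miRNAs in 5 clusters); and a noisy functional
similarity (within ≈ 0.8, between ≈ 0.2) covering 60 % of miRNAs. All
four artifacts are written in exactly the dialects the readers parse, so
synthetic runs exercise the real I/O paths.

What passing tests show: every feature block independently carries the
planted signal, the pipeline recovers it far above the label-permuted
null, and the ablations remain meaningful. What they do not show: real
association networks have heavy-tailed degree distributions, correlated
disease co-annotation and non-random sequence composition, none of which
the block model imitates; absolute metric values on synthetic data do
not transfer to real corpora.

A structural property of these conditions deserves emphasis: with
p_in = 0.6, about 40 % of within-block cells are unassociated, and a
negative sampled from such a cell is *feature-identical* to a
within-block positive. Scoring pairs by the true cluster indicator —
the best any cluster-level feature can do — yields AUC ≈ 0.79 on the
seed-7 benchmark; an RBF-SVM on the full fused features reaches ≈ 0.84
(the kernel entries leak some pair-specific profile information beyond
cluster identity); a logistic model tree given *oracle* splits on the
true disease clusters reaches ≈ 0.80. The shipped tree's ≈ 0.73 should
be read against those ceilings, not against 1.0. On the same benchmark
the sequence-only ablation (DescSeq ≈ 0.78) can edge out the full
descriptor: the planted motif block is noise-free by construction while
the kernel-backed RSim block adds label-noise-correlated attributes —
a property of these synthetic conditions, not of the method.

## Problem sizes

The default benchmark (40×60 grid, ≈ 780 balanced pairs, 164-wide
descriptors, 5-fold CV, four runs including the null and both ablations)
completes in about a minute on one CPU; the complete test suite in
under two. Smoke tests use a 12×18 grid.

## Known limitations

* Two-class only; nominal attributes and missing values are out of scope.
* The skip-gram trainer is a compact reference implementation (pure
  numpy, single-threaded); it is not tuned for corpora beyond the tens
  of thousands of tokens this pipeline produces.
* The ontology reader accepts two-column TSV and MeSH-style ASCII
  descriptor records only; no XML.
* GIP kernels are computed once on the full adjacency matrix before
  cross-validation, as is conventional for this method family; fold-wise
  kernel recomputation is not implemented.
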