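# Methods

## Model

The network maps a tumor's binary somatic-alteration profile and cancer-type
label to genome-wide expression through three interpretable stages.

**Encoder.** Each altered gene id is looked up in a gene-embedding table
(dimension M; default 512, desk-scale runs use 32). A multi-head
self-attention pool scores each altered gene per head,
`beta[g, j] = theta_j . tanh(W0 e_g)`, normalises with a softmax over that
tumor's altered genes only, and sums head weights into per-gene attention
`alpha_g` (so the attention of a tumor's genes sums to the head count `h`).
The tumor embedding is `e_t = e_s + sum_g alpha_g e_g`, where `e_s` is a
learned cancer-type embedding that absorbs tissue-of-origin signal.
Variable-length profiles are padded per batch; padded slots receive a large
negative logit (−1e9) so their softmax weight is exactly zero. A tumor with
no remaining alterations is legal and reduces to `e_t = e_s`. Batches order
each profile's genes canonically (sorted), which makes all outputs bitwise
invariant to the order in which altered genes are listed.

**TF layer.** `e_f = tanh(W_f e_t + b_f)` gives bounded per-TF activity
scores in (−1, 1); these are latent regulatory outputs, not TF mRNA levels.
ReLU is available via config but tanh is the default.

**Constrained decoder.** `yhat = W e_f + b_r` with `W` (genes × TFs)
restricted to the support of the binary chromatin prior `C` and to
non-negative values. Both constraints are *hard*: after every optimizer step
`W` is projected (`W <- max(W, 0) * C`), so masked-out entries are exactly
zero at every point of training, not just at convergence — chosen over a
soft Gaussian-prior penalty or a softplus reparameterisation because the
projection is exact and keeps the TF layer stable across runs.

**Dropout** (rate 0.2) acts at three sites in training mode only: whole
embedded gene slots after the input lookup, the tumor embedding, and the
activated TF layer. Inference is deterministic.

**Initialisation.** Glorot-uniform for `W0`, `theta`, `W_f`; embeddings
N(0, 0.05); decoder uniform on [0, 0.01] inside the mask; zero biases. A
load hook (`CitrusModel.load_gene_embeddings`) accepts externally trained
gene-embedding tables; by default embeddings are random and learned
end-to-end.

The network, analytic backpropagation and Adam are implemented directly in
numpy. Gradients are validated against central finite differences
(relative error < 1e-4 at epsilon 1e-5) in the test suite.

## Training protocol

Adam with lr 1e-3, weight decay 1e-5 (decoupled L2, applied to weight
matrices and embeddings but not biases; masked decoder entries stay zero
because the projection follows every step), batch size 100. Expression is
per-gene z-scored with training-split moments; constant genes are centred
only. Validation loss (MSE) is evaluated once per epoch; early stopping
counts evaluation events, never fires during the first `warmup_evals`
evaluations (180 at full scale), then stops after `patience` (30)
evaluations without a new best, restoring the best checkpoint. Divergence
(non-finite validation loss) aborts with a diagnostic. The held-out test set
is a stratified 20% split with per-type largest-remainder rounding;
hyperparameter selection uses stratified 5-fold CV on the remaining pool.
TF activities are stabilised by averaging an ensemble of 10 runs that differ
only in initialisation and dropout seeds, sharing one train/validation
split.

Desk-scale runs in the tests and the acceptance script use embedding 32 /
attention 16 / 4 heads, warm-up 30 and patience 20 over at most 200 epochs —
sizes chosen so the whole suite exercises the full protocol on simulated
cohorts in minutes; the configuration defaults (512/256/8, warm-up 180,
patience 30, max 1000 epochs) are the full-scale settings.

## Chromatin prior

Coordinates are BED-convention (0-based half-open) throughout. A peak is
assigned to a gene when it overlaps (≥1 bp) the transcription unit extended
by 100 kb on both genomic sides; because "upstream of the TSS" and
"downstream of the 3′ end" name exactly the two genomic sides of the unit on
either strand, the strand-aware and symmetric readings coincide for equal
flanks and a single `flank` parameter is exposed (plus an optional
nearest-TSS-only mode that assigns each peak to a single gene). Per gene and
motif the maximum FIMO score over assigned peaks is kept; a gene–TF edge
enters `C` iff that max-pooled score is positive, i.e. at least one
significant hit (P < 1e-5; re-filtered defensively on load) in an assigned
peak. TFs are dropped when not expressed in ≥50% of samples in any tumor
type, and redundant motifs are collapsed: while any surviving pair's
target-peak Jaccard index exceeds 0.5, the pair with the largest index is
examined and the member with the larger mean Jaccard against all survivors
is removed (lexicographic tie-break, removing the larger id). The iteration
runs to convergence and is idempotent. TFs that survive with an all-zero
column are retained but logged. The prior is pan-tissue by construction.

## Interpretation statistics

- **Evaluation**: Spearman rank correlation between predicted and measured
  expression per tumor (average ranks on ties); constant profiles yield NA
  and are excluded from the mean with a warning.
- **Attention summaries**: per gene, cumulative attention = sum of
  summed-head weights over carrier tumors (per-carrier mean available).
  Driver enrichment splits genes at `log(attention + 1) >= 2` (natural log,
  configurable) and applies a two-sided Fisher exact test against driver
  membership; a top-100-most-frequent variant splits the frequent genes at
  the same threshold.
- **In silico knockout**: for an alteration with ≥5 carriers, carrier tumors
  are re-scored with the gene deleted; per TF, a two-sample t-test compares
  original vs deleted activities (ensemble-averaged), BH-corrected within
  the TF panel per alteration (global pooling optional). Welch's form is the
  default (pooled-variance and paired forms available). The knockout uses
  the trained model's forward pass only; no retraining.
- **TF/tumor-type association**: one-vs-rest t-tests per (type, TF),
  BH within each type's TF family, direction from the mean difference.
- **Subtypes**: k-means (seeded, 10 restarts) on TF-activity rows of one
  cancer type; average-linkage Euclidean hierarchical clustering orders
  subtypes and TFs for display; a silhouette scan assists choosing k.
- **Alteration–subtype association**: per (alteration, subtype) a 2×2
  Fisher test of carriers inside vs outside the subtype, BH across subtypes
  within the alteration, and a signed score
  `direction × (−log10 FDR)` (+1 when the within-subtype carrier frequency
  is higher).

## Affinity-regression baseline

The bilinear model `D W P^T ~ Y` (genes × TFs attribute matrix `D`,
tumors × alterations matrix `P`) is fit as a single-penalty ridge regression
on `vec(W)`. The normal equations factor over the Kronecker structure:
with `D^T D = U diag(s) U^T` and `P^T P = V diag(t) V^T`, the solution is
`W = U [ (U^T D^T Y P V) / (s_i t_j + lambda) ] V^T`, so the Kronecker
product is never materialised; the factored solve is verified against the
explicit `(P ⊗ D)` ridge solution in tests. One model per cancer type;
lambda tuned by 5-fold CV on training tumors; evaluation uses the shared
per-tumor Spearman metric. Two-sided (separate row/column) penalties are out
of scope.

## Synthetic cohorts

The generator mirrors the model class (well-specified by default). Defaults
define the reference condition used across the tests: 600 tumors, 3 cancer
types, 400 expression genes, 1000 candidate alteration genes, 30 TFs, 6
drivers with per-type carrier frequencies drawn from [0.15, 0.40], each
driver shifting 3 random TFs by ±1.5 before the tanh link; cancer types add
N(0, 1) per-TF offsets; expression is the masked non-negative readout
(prior density 0.10, at least one TF per gene, weights scaled by
3/sqrt(row degree)) plus N(0, 0.5) noise around gene baselines N(8, 1) on
log scale. Background alterations are inert; their per-gene rates are
lognormal (sigma 1.25) around a 1% mean, a heavy-tailed spectrum like real
cohorts — under a uniform 1% rate essentially no background gene would
survive the pre-processing filter (genes altered in <4% of samples of every
cancer type are removed, as for the real data) and ranking analyses would
have no background to rank against. A `misspecify` flag adds pairwise
driver-interaction terms that violate the additive generative assumption.
Everything is driven by one seed and is byte-reproducible.

What the simulations do *not* emulate: mutational signatures and
hotspot structure, CNV segment geometry, tumor purity and stromal
admixture, expression heteroskedasticity, and motif-family redundancy in
the prior. Passing tests therefore demonstrate correctness of the
algorithms and recoverability of planted signal under the model's own
assumptions, not performance on real tumors.

## Numerical and degenerate-case conventions

- Softmax uses max-shift stabilisation; padded slots contribute exactly 0.
- Zero-carrier tumors return the cancer-type embedding; deleting a gene
  from a non-carrier is a no-op.
- t-tests with zero variance in both groups and equal means report t = 0,
  p = 1 (rather than NaN).
- BH/Bonferroni propagate NaN inputs as NA; adjusted values are clipped at 1.
- sd = 0 genes are centred only; their z-scores are 0.
- Jaccard of an empty target set is 0 against everything.
- Fisher tests with an empty margin report p = 1 with a warning.

## Known limitations

The in silico knockout compares the *same* carrier tumors with and without
the deleted gene. Under a true null this makes the unpaired t-test strongly
conservative — the two groups are near-perfectly correlated, so p-values
concentrate near 1 instead of being uniform; on a no-effect cohort the
procedure makes (correctly) no FDR < 0.05 discoveries, but its raw p-values
should not be read as calibrated evidence measures. Motif-sharing TF
families remain unresolvable by construction of the prior, and the prior
does not encode activation vs repression, so activity signs reflect the
dominant learned direction over targets.
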