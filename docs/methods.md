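# Methods

This note documents the model, the numerical and design choices behind the
implementation, what the synthetic generator does and does not emulate,
and the known limitations. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Model and assumptions

The method treats miRNA–disease association prediction as link prediction
on a heterogeneous graph. Its core assumption is the standard
guilt-by-association hypothesis: similar miRNAs associate with similar
diseases, where "similar" is measured from several complementary sources
(function, sequence, family, interaction profiles, ontology semantics).
Each source is a similarity view; none is trusted a priori, and softmax-
parameterized fusion weights (`α` for the five miRNA views, `β` for the
three disease views) are learned jointly with the network so that the
model itself decides the views' contributions. Association entries are
modeled as conditionally independent Bernoulli variables given the node
embeddings; unknown pairs are treated as negatives, so label noise from
undiscovered true associations is inherent to the benchmark.

### Similarity views

- **Sequence** (miRNA): `1 − Levenshtein(s_i, s_j)/max(|s_i|, |s_j|)`,
  computed with edlib. Note that Levenshtein on equal-length binary or RNA
  strings is *not* the Hamming distance: insertions/deletions can realign
  (e.g. `1010` vs `0101` has distance 2, not 4).
- **Family** (miRNA): indicator of shared family label; unannotated
  miRNAs match nothing off-diagonal. Diagonals are 1 by convention.
- **Functional** (miRNA): loaded, not computed; symmetrized and clipped
  to [0, 1] on ingest.
- **GIP** (both): `exp(−λ‖P_i − P_j‖²)` on association profiles, with
  bandwidth `λ = λ′ /` (mean squared profile norm), `λ′ = 1`. For a
  disease with an all-zero profile (e.g. a held-out disease) the kernel
  degenerates to `exp(−λ‖P_j‖²)` — a pure degree effect with no block
  information; this matters for the hold-out protocol (below).
- **lncRNA profile** (both): Levenshtein on the 0/1 interaction profile
  strings, normalized by profile length. Because profiles of unrelated
  entities still agree at most positions, this view has a high background
  floor (~0.8 at the default densities) and small contrast; the fusion
  weights reliably learn to discount it.
- **Semantic** (disease): per-disease MeSH-style DAG with child→parent
  edges, the disease term being the most specific node. Scheme 1 assigns
  the disease term contribution 1 and each ancestor `μ·max(children)`
  (decay `μ = 0.5`); scheme 2 weighs a term by `−ln(countDAGs(t)/N)`
  (natural log; the base only rescales the score uniformly). Pair
  similarity is the shared-ancestor contribution sum normalized by the
  diseases' total semantic values, averaged over the two schemes.
  Diseases with empty DAGs get similarity 0 to all others and 1 to self.

All computed views are forced symmetric (averaging with the transpose),
unit-diagonal, and clipped to [0, 1], in double precision.

## Network construction

The integrated similarities and the association matrix form the block
adjacency `M = [[Mm, A], [Aᵀ, Md]]`. Initial node features come from
random walk with restart run simultaneously from every node:
`D(k) = (1−r)·An·D(k−1) + r·I` with `An` the column-normalized adjacency
(transition-matrix convention), restart `r = 0.5` (not fixed by the
method's description; exposed in `RwrConfig`), tolerance `1e-6` on the
Frobenius difference, and a self-loop added to isolated nodes. Column `t`
of the converged matrix is node `t`'s diffusion profile and sums to 1.

Two numerical choices precede training:

- **Adjacency normalization.** The graph convolutions use the
  symmetrically normalized adjacency `D^{−1/2} M D^{−1/2}` by default
  (`ModelConfig.normalize_adjacency`). With the raw adjacency the row
  sums are ~40 at the default problem size, activations saturate
  (float32 sigmoid overflow) and learning stalls; normalization is the
  GCN convention for exactly this reason. The switch can be turned off.
- **Feature preconditioning.** The RWR matrix has entries of order `1/N`
  plus a large restart mass `≈ r` on the diagonal. Inside training the
  diagonal is zeroed (it is a pure node-identity channel that invites
  memorization of training pairs) and the matrix is scaled by `N` so the
  features are O(1), matching the scale Glorot-initialized layers expect.
  The public `rwr_features` contract (column-stochastic output) is
  unchanged; preconditioning happens in `train_model`.

Fusion weights receive gradients through the adjacency: the full block
matrix is rebuilt from the current softmax weights at every optimization
step (training is full-batch, so "per step" and "per epoch" coincide).
The RWR features are computed once from the uniform-weight fusion and
held constant — differentiating through the iterative solver would
dominate the cost for no measured benefit.

## Architecture

ECA recalibration → GCN layer 1 → multi-head self-attention → GCN layer 2
→ adaptive layer fusion → pair MLP.

- **ECA**: channel weights `σ(Conv1D(channel means))`, kernel size from
  the standard adaptive rule (nearest odd to `|log₂(C)/2 + 1/2|`; 5 at
  the default 160 channels), no bias, no residual (a residual switch
  exists, off by default; the method description mentions a skip
  connection only ambiguously).
- **GCN layers**: `ReLU(M·H·W)`, embedding size 256, two layers.
- **Attention**: 4 heads of width 64 (the head count is not stated by
  the method's description; 4 is the common default), scaled dot-product
  with row softmax, heads concatenated then projected by `W_O`.
- **Layer fusion**: `γ₁H(1) + γ₂H(2)` with `(γ₁, γ₂)` softmax-mapped.
- **MLP**: concat(h_m, h_d) (512) → 256 ReLU → 1 → sigmoid. The hidden
  layer is evaluated as `h_m·W_top + h_d·W_bottom` with per-node
  projections precomputed — algebraically identical to the concatenation
  form but O(N·d²) instead of O(pairs·d²) per epoch.
- **Ablations** (config flags): `attention` disables ECA and the
  self-attention; `egcn` disables only the self-attention between the
  convolutions; `multisource` collapses each side's views to the GIP
  kernel alone.

Everything is implemented over a small reverse-mode autodiff engine
(`mvhagcn._tensor`) in NumPy — no deep-learning framework is required at
runtime; the engine is gradient-checked against central finite
differences in the test suite. Model training runs in float32 (halves CPU
time; all similarity/network math stays float64).

## Optimization

Adam with learning rate 5e-4, weight decay 5e-4 (coupled, added to the
gradient), 2000 epochs by default, full batch, BCE loss with scores
clipped to `[1e-7, 1−1e-7]`. The eight fusion raw weights form a second
Adam group with step 0.05 under cosine annealing to 0: their gradients
are averaged over the whole adjacency and are orders of magnitude smaller
than layer-weight gradients, so with a shared step they stay effectively
uniform for hundreds of epochs and the multi-view fusion never engages;
the annealing makes the mixing weights genuinely converge by the final
epochs. Parameters are initialized with a seeded symmetric-uniform
(Glorot) scheme; all randomness flows from explicit integer seeds and
repeated runs are bit-for-bit identical.

## Evaluation protocol

5-fold cross-validation partitions the known positives; negatives are
sampled 1:1 uniformly without replacement from unknown pairs, disjoint
across folds. Per fold, test positives are zeroed in the association
matrix *before* the GIP kernels, the adjacency and the RWR features are
computed — an audit asserts per fold that no test positive reaches any
training-time quantity. AUC uses the rank statistic with average tie
handling, AUPR the precision–recall step sum, ACC a 0.5 threshold (the
threshold is a convention; the method's description reports ACC without
one). The disease-wise hold-out removes every association of the target
disease before any similarity or graph construction, retrains from
scratch, and ranks all miRNAs; ties break by lexicographic miRNA id.

## Synthetic data

The generator plants one latent block assignment (uniform over 5 blocks
by default, 100 miRNAs × 60 diseases) and derives every input from it:
associations are Bernoulli(0.30) inside matched blocks and
Bernoulli(0.02) outside; families equal miRNA blocks; sequences are
per-block ancestors (22 nt) with 3 point substitutions per member; the
functional matrix is the block indicator plus symmetrized Gaussian noise
(sd 0.05); each disease's DAG hangs off its block's small term subtree
under one shared root, so semantic similarity is elevated within blocks;
lncRNA profiles (40 lncRNAs, interaction probability 0.40 for the block's
preferred lncRNA group vs 0.05 otherwise) are block-correlated. A single
seed drives all sub-generators through a splitting scheme, and
`planted_truth` returns the latent labels.

**What passing tests show — and don't.** Because associations are
conditionally independent given the blocks, the Bayes-optimal ranking on
this generator is the block indicator, whose expected 5-fold AUC at the
default rates is ≈0.82 (positives are within-block with probability
360/456 ≈ 0.79, sampled negatives with probability 840/5544 ≈ 0.15).
Recovery scores must be read against that ceiling, not against 1.0; the
full model reaches ≈0.78 and, as designed, beats its single-view (GIP-
only) ablation. Real association data has degree heterogeneity, nested
disease categories and much sparser profiles, none of which the generator
emulates — synthetic results demonstrate mechanism, not clinical
performance. The hold-out ranking demonstration uses fewer, larger blocks
(3 blocks over 45×15) because a held-out disease is scored purely through
its similarity row: with many small blocks the handful of in-block peers
is swamped by the background-similarity floor of the unrelated majority
(the GIP view is pure degree noise for a zero-profile disease), and even
an oracle propagation scorer shows no enrichment at the default shape.

## Numerical details and degenerate inputs

- Similarity ingest tolerates asymmetry up to 1e-8, then symmetrizes
  exactly; entries outside [0, 1] beyond 1e-12 are rejected for computed
  views and clipped for loaded ones.
- An all-zero association matrix makes the GIP bandwidth undefined and is
  rejected; the synthetic generator retries once with a derived seed.
- RWR raises after 1000 iterations without convergence, reporting the
  residual; `r = 1` short-circuits to the identity.
- BCE is computed on clipped scores; gradients pass only through
  unclipped entries.
- Ranking ties break by lexicographically smaller miRNA id, making every
  output file deterministic.

## Limitations

- Dense O(N²) propagation and attention: fine to a few thousand nodes,
  unsuitable beyond without sampling or sparse attention.
- The fusion weights' larger optimizer step is a pragmatic choice; a
  principled alternative (e.g. natural-gradient scaling) was not explored.
- Scoring a disease (or miRNA) with no known links relies entirely on its
  similarity row; when that row's contrast is weak the ranking degrades
  toward a popularity baseline, as quantified above.
- Unknown pairs serve as negatives both in training and evaluation; all
  reported metrics inherit that approximation.
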