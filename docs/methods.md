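# Methods

## Problem and model

`mifam` predicts binary drug–target interactions (DTI). Every drug and every
protein target is described by two complementary feature views:

* **Drugs** — a 202-dimensional physicochemical descriptor vector (PCP) and
  the 167-bit MACCS structural-key fingerprint, both computed from SMILES
  with RDKit.
* **Targets** — an 800-dimensional gapped dipeptide composition (DC) and a
  per-protein embedding from a protein language model (PLM), mean-pooled
  over residues.

Each view is PCA-reduced to a common dimension (default 128), the two views
of an entity type are concatenated into its fused feature vector, and a
binary similarity graph per view (cosine similarity thresholded at `tau`)
is fused by elementwise logical OR. The fused features and fused graph feed
a per-entity-type encoder of `n_blocks` (default 2) identical blocks:

1. **GAT stack** — `n_gat_layers` (default 4) graph-attention layers. For
   layer input `h`, attention logits are `e_ij = a·[W h_i ‖ W h_j]` for
   `j ∈ N_i ∪ {i}`, passed through LeakyReLU (slope 0.2) and a softmax
   restricted to the neighbourhood; the layer output is
   `ReLU(Σ_j α_ij W h_j)` per head, heads concatenated. The outputs of all
   layers are concatenated column-wise into `V_GAT`, whose width is
   `n_gat_layers × gat_heads × hidden_units` (64 at defaults).
2. **MHSA** — multi-head scaled-dot-product self-attention over the entity
   rows of `V_GAT` (`softmax(QKᵀ/√d_K)V` per head). The head outputs are
   averaged, and the block output is the average of that mean with `V_GAT`
   itself, so the block preserves width.

A pair is scored by concatenating the two final 64-dim entity embeddings
and applying a 3-layer MLP (hidden sizes 256 and 64, ReLU; sigmoid output).
Training minimizes mean squared error with Adam.

## Default hyperparameters

| parameter | default | notes |
|---|---|---|
| epochs / patience | 15 / 5 | early stopping on a stratified 10% validation split of the training pairs |
| learning rate | 1e-4 | Adam |
| batch size | 128 | shuffled pair mini-batches; the graphs are always full |
| hidden units | 16 | per GAT head and layer |
| GAT layers / heads | 4 / 1 | head count is a config knob; the published table fixes only the MHSA head count |
| MHSA heads | 4 | `d_k = d_model` so head outputs are width-compatible with the residual average |
| LeakyReLU slope | 0.2 | attention logits only |
| PCA dimension | 128 | capped at `min(d, n−1)` with a warning |
| similarity threshold `tau` | 0.5 | see below |
| blocks | 2 | ablation knob `n_blocks` |

## Design choices where the design was open

* **Graph binarization.** OR-fusion requires binary adjacency matrices, but
  no thresholding rule for the cosine similarities is fixed a priori; we
  threshold at `tau = 0.5` and always add self-loops (every node must
  attend at least to itself). `tau` is exposed in the config/CLI, and a
  symmetrized top-k mode is available for regimes where a global threshold
  makes the graph degenerate.
* **MHSA head combination.** Inside a block the head outputs are averaged
  and then averaged again with `V_GAT` (a residual-style combination that
  preserves width). A plain concatenation mode is kept in
  `mhsa_forward(..., combine="concat")` for standalone use.
* **DC normalization.** "Frequency" is normalized per gap block: the gap-0
  block divides by the number of adjacent pairs, the gap-1 block by the
  number of skip pairs, so each block sums to 1 independently of sequence
  length. Pairs containing non-standard residues (X, B, Z, U, O) are
  excluded from numerators and denominators.
* **PLM pooling and fallback.** Per-residue PLM representations are
  mean-pooled (the standard reduction for this model family; CLS pooling is
  not offered). The PLM backend is pluggable via `set_plm_backend`; the
  default embedder is a deterministic signed bag-of-3-mers hash projection,
  L2-normalized, which keeps the whole pipeline runnable offline. It is a
  sequence-composition feature, not a learned representation: tests passing
  with it say nothing about PLM embedding quality.
* **Descriptor manifest.** RDKit's descriptor list drifts across releases,
  so the 202 descriptor names are frozen (lexicographic order) in
  `drug_featurization.PCP_MANIFEST`; the 2-D BCUT family is excluded
  because it can be undefined for molecules without assignable partial
  charges. Non-finite descriptor values are replaced by 0 with a warning so
  PCA always receives finite input.
* **Transductive protocol.** PCA and the similarity graphs are fit on the
  full entity sets before pairs are split into CV folds; only the labelled
  pairs are partitioned. This mirrors the pipeline ordering the model was
  designed for, and it shares unlabelled feature information (not labels)
  across folds — a caveat to remember when comparing against strictly
  inductive protocols.
* **AUC/AUPR conventions.** AUC is the rank statistic with half credit for
  ties; AUPR uses step-wise interpolation (average precision), which avoids
  the optimistic bias of trapezoidal interpolation over precision.
* **Numerics.** All softmaxes subtract the row maximum before
  exponentiation. PCA component signs are fixed by making each component's
  largest-magnitude loading positive. All randomness flows through
  `numpy.random.default_rng(seed)`.

The model core (GAT, MHSA, MLP, Adam) is implemented directly on NumPy with
a small reverse-mode autodiff engine (`mifam._autodiff`); the brute-force
oracles in the test suite check the vectorized forward passes
equation-by-equation, and gradient correctness is exercised end-to-end by
the loss-decrease and signal-recovery tests.

## What the synthetic generator emulates — and what it does not

`synthetic_data.generate_world` emulates the *structure* of DTI benchmark
data: two feature views per entity with planted cluster structure
(per view, cluster centroids drawn from a standard normal; entity vectors =
centroid + isotropic Gaussian noise), interaction labels driven by a
drug-cluster × target-cluster compatibility matrix, and negatives sampled
uniformly from unused pairs at a 1:1 ratio — the same blind negative
sampling used when true negatives are unknown.

The default world is 200 drugs × 200 targets in 4×4 balanced clusters,
view dimensions (202, 167, 800, 256), noise_sd 0.1, 1,000 positives, seed
7. The default compatibility matrix has exactly two interacting cells,
`(0,0)` and `(1,1)`. This sparsity is deliberate: because negatives are
drawn blindly from unused pairs, some negatives inevitably fall in
compatible cells and are indistinguishable from positives. With two
compatible cells ~10% of negatives are such collisions, so the Bayes-optimal
AUC of the labelling process is ≈ 0.95 and a well-functioning pipeline can
reach the 0.9 acceptance bar; with a full diagonal the Bayes ceiling drops
to ≈ 0.885 and no model could pass. The generator is feature-level: it
bypasses SMILES/sequence chemistry entirely, carries no feature
correlations, batch structure or class imbalance, and its clusters are far
cleaner than real chemotype/protein-family structure. Passing tests on it
demonstrate that the pipeline recovers planted relational signal, not that
it matches published benchmark performance on real data.

The ablation checks use a deliberately harder variant (120×120 entities,
16-dim views, noise_sd 1.2, 600 positives): with low-dimensional noisy
views a single view misassigns some entities, so the benefit of fusing two
independent views — and of a second encoder block — is measurable rather
than lost in the ceiling.

## Problem sizes used by the tests and the acceptance script

The test suite runs the full 10-fold CV on the default world at reduced
epochs (6 for the signal run, 3 for the label-shuffled null), which
preserves the ranking behaviour at a fraction of the cost; unit tests use a
40×40 world. `scripts/acceptance.py` runs the default world at the full
default training settings (15 epochs, patience 5) and the null at 5 epochs.
All reported numbers are recomputed at run time from the seed passed on the
command line.

## Known limitations

* The hash embedder is order-sensitive but captures only local 3-mer
  composition; swapping in a real PLM backend changes the embedding view's
  information content entirely.
* The transductive protocol leaks unlabeled feature structure across folds
  (by design); entity-disjoint splitting is not implemented.
* Full-graph encoding at every optimizer step is quadratic in entity count
  per layer; the implementation targets desk-scale datasets (thousands of
  entities), not web-scale screening.
* MSE on sigmoid outputs (rather than cross-entropy) follows the model's
  published formulation; it trains more slowly near saturated scores.
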