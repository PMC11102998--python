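# mifam

Drug–target interaction (DTI) prediction from fused multi-source features
with graph attention and multi-head self-attention.

Identifying which compounds bind which proteins is a central step in drug
discovery and repositioning. `mifam` is a desk-scale, pure-Python
implementation of a multi-source-fusion attention model for this task,
aimed at computational chemists and method developers who want every stage
— featurization, similarity-graph fusion, the attention encoder, training
and evaluation — inspectable, deterministic and runnable offline on a
laptop CPU.

## Model

Each drug is described by a 202-dim physicochemical descriptor vector and
the 167-bit MACCS fingerprint (both from SMILES via RDKit); each protein by
an 800-dim gapped dipeptide composition and a language-model embedding
(pluggable backend; a deterministic k-mer hash embedder ships as the
default). Per entity type:

1. each view is PCA-reduced to 128 dims; the two reduced views are
   concatenated into the fused feature matrix `X`;
2. per view, a binary similarity graph is built by thresholding cosine
   similarity (`S(A,B) = A·B / (|A||B|)`, edge iff `S ≥ τ`, self-loops
   kept) and the two graphs are fused by elementwise logical OR;
3. an encoder of two blocks runs on `(X, A)`. Each block stacks 4 GAT
   layers — `α_ij = softmax_j(LeakyReLU(a·[Wh_i ‖ Wh_j]))` over the
   neighbourhood, `h'_i = ReLU(Σ_j α_ij W h_j)` — concatenating the layer
   outputs into `V_GAT` (width 64 at defaults), then applies multi-head
   self-attention `softmax(QKᵀ/√d_K)V` over the entity rows and averages
   the head mean with `V_GAT`.

A pair score in (0, 1) comes from a 3-layer MLP with sigmoid output on the
concatenated drug and target embeddings; training minimizes MSE with Adam
(lr 1e-4, batch 128, 15 epochs, early stopping with patience 5).
Evaluation is stratified 10-fold cross-validation over labelled pairs with
AUC, AUPR, precision, recall and F1. See `docs/methods.md` for the full
account, defaults and design decisions.

## Worked example

Everything runs on self-contained synthetic worlds (no downloads); the
generator plants cluster structure in two feature views per entity and
draws labels from a cluster-compatibility matrix with 1:1 negatives.

```bash
mifam simulate --seed 7 --out world/
mifam cv \
  --drug-view1 world/drug_view1.tsv --drug-view2 world/drug_view2.tsv \
  --target-view1 world/target_view1.tsv --target-view2 world/target_view2.tsv \
  --pairs world/pairs.tsv --seed 7 --folds 10 --out report.json
```

On the default world (200 drugs × 200 targets, 4×4 clusters, 2,000 pairs)
this trains ten models and writes per-fold and mean metrics; with seed 1
the mean block of `report.json` reads:

```json
"mean": {"auc": 0.9489, "aupr": 0.9081, "precision": 0.9005,
         "recall": 1.0, "f1": 0.9475}
```

A mean AUC of ≈ 0.95 is the ceiling this world's labelling process allows
(about 10% of the blindly sampled negatives fall in interacting cluster
cells and cannot be distinguished), so the pipeline is recovering
essentially all of the planted signal; shuffling the labels drops the mean
AUC to ≈ 0.50, confirming the signal is real rather than an artifact of
the protocol. From Python the same run is:

```python
from mifam import WorldConfig, generate_world, run_cv, TrainConfig
from mifam.fusion_graph import build_fused_inputs
from mifam.training_evaluation import EntityInputs

world = generate_world(WorldConfig(seed=1))
drugs = EntityInputs(*build_fused_inputs(*world.drug_views))
targets = EntityInputs(*build_fused_inputs(*world.target_views))
report = run_cv(world.pairs, drugs, targets, TrainConfig(seed=1), k=10)
print(report.mean)
```

Real inputs work the same way via `--drugs drugs.tsv` (columns
`id`, `smiles`) and `--proteins proteins.fasta`; `mifam train` /
`mifam predict` save and apply a checkpoint, `mifam featurize-drugs`,
`mifam featurize-proteins` and `mifam build-graph` expose the individual
stages.

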