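# dtifuse

Multi-modal prediction of protein–compound (drug–target) interactions by
fusing **molecular structure** features with **interactome** features.

Virtual screening methods that rely only on molecular structure — amino-acid
sequences and chemical fingerprints — degrade sharply on *cold-start*
problems, where the test compounds (or both test proteins and compounds)
never appear in training. Interaction networks carry a complementary signal:
proteins with similar interaction partners, and compounds with similar
activity profiles, tend to share binding behaviour even when they look
nothing alike in sequence or structure. `dtifuse` implements an end-to-end
pipeline that exploits both signals, together with the benchmark
construction, cold-start cross-validation splits, evaluation suite, and the
structure-versus-network similarity analysis needed to study them.

## The model

Each protein *p* is represented by the concatenation of

* **a**ₚ — the output of a 1D convolutional encoder over the one-hot
  sequence matrix (20 × L alphabet `ACDEFGHIKLMNPQRSTVWY`): stacked
  convolutions with Leaky-ReLU and average pooling, finished by a global
  max pool over non-padding positions;
* **N**ₚ — its node2vec embedding in the protein–protein interaction (PPI)
  network (second-order biased random walks + skip-gram with negative
  sampling; defaults d = 128, walk length 80, 10 walks/node, p = q = 1,
  weighted transitions).

Each compound *c* is represented by its 1024-bit radius-2
extended-connectivity fingerprint (ECFP) **b**_c concatenated with its
node2vec embedding **N**_c in the compound–compound interaction (CCI)
network. Fully connected maps *f*, *g* project both sides into a shared
latent space of dimension *d*, and the interaction score is a learnable
extension of cosine similarity:

```
score(p, c) = σ( h( f(v_p) ⊙ g(v_c) ) ),   v_p = [a_p ‖ N_p],  v_c = [b_c ‖ N_c]
```

with ⊙ the element-wise product and *h* a fully connected output layer.
A pair is called interacting when score > 0.5 (strict). Training minimizes
mean binary cross-entropy plus an L2 penalty λ·Σw²/2 with mini-batch Adam;
batch normalization follows each convolution and dropout follows the latent
maps. Single-modality variants (`molecular`, `network`) apply *f*, *g* to
their sole feature vector.

Benchmark data follow the STITCH/STRING flat-file dialect: link tables with
per-channel confidence scores 0–1000, filtered at score ≥ 700 for
protein–compound interactions and ≥ 150 for the PPI and CCI channels, with
negatives sampled uniformly from unobserved pairs at a 1:2
positive:negative ratio. Three split designs are provided: **baseline**
(random pairs), **unseen compound** (no compound shared across folds), and
**hard** (neither proteins nor compounds of a test fold appear in its
training set), each with a leakage audit.

A self-contained synthetic benchmark generator plants complementary
community structure (stochastic-block-model networks, sequence motifs,
fingerprint templates, a hidden compatibility matrix) so every stage is
testable without database downloads.

## Worked example

```python
from dtifuse import (SyntheticConfig, generate_benchmark, WalkConfig,
                     embed_network, FusionModel, TrainingConfig,
                     split_baseline, auroc)
from dtifuse.protein_features import CnnConfig

bench = generate_benchmark(SyntheticConfig(
    n_proteins=60, n_compounds=60, n_pairs=600, seed=1))
walk = WalkConfig(dimensions=32, walk_length=40, num_walks=10,
                  window=5, epochs=5, seed=1)
prot_emb = embed_network(bench.ppi, walk)
comp_emb = embed_network(bench.cci, walk)

folds = split_baseline(bench.pairs, k=5, seed=1)
train, test = folds.train_pairs(0), folds.test_pairs(0)

model = FusionModel(
    train, mode="integrated",
    sequences=bench.sequences, fingerprints=bench.fingerprints,
    protein_embeddings=prot_emb, compound_embeddings=comp_emb,
    config=TrainingConfig(epochs=80, batch_size=64, latent_dim=32,
                          dropout=0.2, cnn=CnnConfig(layers=((16, 7), (16, 5))),
                          seed=1))
results = model.fit()
scores, labels = results.predict(test)
print(results.summary())
print("test AUROC:", round(auroc(scores, test.frame["label"]), 3))
```

Output (abridged):

```
Protein-compound interaction fusion model
============================================
mode:            integrated
training pairs:  480 (161 positive)
latent dim d:    32
CNN:             ((16, 7), (16, 5)) filters, max_len 80, fp dim 256
embeddings:      protein d=32, compound d=32
optimizer:       Adam lr=0.001, batch=64, l2=0.0001, dropout=0.2
epochs run:      80 (best epoch 72)
final train loss 0.0351
final val loss   0.4354
test AUROC: 0.867
```

The AUROC of 0.87 on held-out pairs (against 0.80 and 0.77 for the
molecular-only and network-only variants of the same run) shows both
modalities contributing: the planted label signal is split between network
communities and sequence/fingerprint motifs, and only the fused model sees
both.

The same pipeline is scriptable from a shell via the `dtifuse` command
(`simulate`, `prepare`, `embed`, `split`, `train`, `evaluate`, `analyze`);
every run directory contains a `run_manifest.json` with the command,
parameters, seeds and input digests.

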