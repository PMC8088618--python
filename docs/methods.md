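# Methods

## Model

`dtifuse` scores a protein–compound pair by projecting a protein feature
vector and a compound feature vector into a common latent space and
measuring a learnable similarity there.

**Protein side.** The amino-acid sequence is one-hot encoded over the fixed
alphabet `ACDEFGHIKLMNPQRSTVWY` (20 rows × `max_len` columns; the order is
part of the model contract and stored with checkpoints). Nonstandard codes
(B, J, O, U, X, Z) become all-zero columns; longer sequences are truncated
with a warning; shorter ones are right-padded with zero columns. The
encoder applies blocks of {1-D convolution (full-height filters) → batch
normalization → Leaky-ReLU (slope 0.01) → non-overlapping average pooling
(window 2)} and finishes with a global max pool restricted to valid
positions. Valid lengths are threaded through every layer
(`l → l − r + 1` per convolution of width `r`, `l → ⌊l/2⌋` per pool), so the
encoding of a sequence is identical whatever the padding width; batch-norm
statistics are likewise computed over valid positions only. The default
architecture is two layers of 64 filters (widths 7 and 5); all of it is
configurable, and the desk-scale studies below use two 16-filter layers.
`max_len` defaults to the longest training sequence.

**Compound side.** Extended-connectivity (Morgan) fingerprints, radius 2,
folded to 1024 bits, computed with RDKit. The synthetic benchmarks instead
supply template-derived binary fingerprints directly (see below); the model
accepts any fixed-length compound feature vector.

**Interactome side.** Both the protein–protein and compound–compound
networks are embedded with node2vec: second-order biased random walks
(return parameter p, in-out parameter q, transition probability
proportional to edge weight; p = q = 1 by default, reducing to a weighted
first-order walk) followed by skip-gram with negative sampling over the
walk corpus. Skip-gram hyperparameters unclaimed by the walk design are
the standard defaults: window 10, 5 negative samples from the
unigram^0.75 distribution, 5 epochs, initial learning rate 0.025 with
linear decay. Training is mini-batched (128 pairs); gradients that collide
on the same node row within a batch are averaged, not summed, which keeps
the effective per-row step equal to per-pair SGD — with summed updates the
trainer diverges on dense small graphs. Embeddings are deterministic given
the seed (single-threaded numpy).

**Fusion and output.** With `a` the CNN encoding, `b` the fingerprint and
`N_p`, `N_c` the two embeddings, the integrated model computes

    x = f([a ‖ N_p]),  y = g([b ‖ N_c]),  score = σ(h(x ⊙ y))

where f, g are single affine maps into a latent space of dimension d
(default 128; one fully connected layer per side, depth configurable), ⊙ is
the element-wise product, and h is an affine output layer — an extension of
cosine similarity whose per-dimension weights are learned. Single-modality
variants feed f and g their sole feature vector. The decision rule is
score > threshold (default 0.5, strict: a tie is negative).

## Training

Loss: mean binary cross-entropy plus λ·Σw²/2 over the convolutional and
fully connected weights and biases (batch-norm scale/shift excluded, since
penalizing them fights the normalization itself). Optimizer: mini-batch
Adam (default lr 1e-3, batch 128; the studies use batch 64). Dropout
(default 0.5; studies use 0.2) follows the latent maps f and g and is
disabled at inference; batch norm uses running statistics at inference.
Scores exactly 0 or 1 in the loss are clipped at 1e-12.

Three further numerical choices proved necessary:

* **Feature standardization.** Each non-CNN input block (fingerprints and
  both embedding tables) is standardized per dimension with training-set
  statistics, frozen at fit time and reused at prediction. Without it the
  embedding block enters f and g at roughly 1/20 the scale of the
  fingerprint block and the network modality is effectively silenced early
  in training.
* **Gradient clipping.** The global gradient norm is clipped at 5.0
  (configurable; 0 disables). Rarely, the element-wise-product head
  amplifies a batch gradient enough to destabilize Adam.
* **Early stopping on validation AUROC.** 10% of the training pairs are
  held out; training stops after `patience` epochs without AUROC
  improvement and the best-epoch parameters are restored. Validation
  *cross-entropy* is recorded but deliberately not used as the stopping
  signal: under label noise (which the synthetic benchmarks possess by
  construction) BCE rises monotonically as scores saturate even while
  ranking quality still improves, and stopping on it restores near-initial
  weights. Setting `validation_fraction = 0` trains for the full epoch
  budget (used by the capacity test).

Training is deterministic given the seed: identical final losses across
runs.

## Benchmark construction

Link tables are whitespace/tab-delimited with a header naming the
confidence channels (STITCH/STRING dialect). Filtering keeps rows whose
named channel score is ≥ the threshold (protein–compound 700, PPI 150,
CCI 150 by convention); edge weight is score/1000, mapping the 0–1000
confidence scale into (0,1]. Self-loops and zero-score rows are dropped
with a warning; duplicate edges (either direction) collapse to one
undirected edge keeping the maximum score. Negatives are drawn uniformly
without replacement from unobserved protein×compound pairs at ratio 2
negatives per positive (round-half-up), and the labelled set is restricted
to pairs whose protein has both a PPI node and a sequence and whose
compound has both a CCI node and a structure.

Split designs: **baseline** — uniform random k folds (sizes differ ≤ 1);
**unseen compound** — compounds partitioned into k groups balanced by pair
count (seeded shuffle + greedy largest-first), a pair's fold is its
compound's group; **hard** — proteins and compounds independently
partitioned the same way, fold i tests on pairs in protein group i AND
compound group i and trains on pairs in neither. A hard-fold pair with
mixed group membership would leak one entity into training, so it is
excluded from that fold entirely (per-fold exclusion; a global-discard
variant is a one-line change in user code by intersecting folds). Every
assignment can be audited (`audit_leakage`), and the cross-validation
driver refuses unaudited-leaky assignments.

## Evaluation

AUROC is the Mann–Whitney probability that a random positive outscores a
random negative, ties counted ½ (rank-based, exact). AUPRC uses step-wise
average-precision integration — the sum over recall increments of
precision at each distinct threshold — rather than trapezoidal
interpolation, which is optimistic for PR curves. F-measure and accuracy
use the strict score > 0.5 rule; F is defined 0 when precision + recall
is 0. Cross-validation reports per-fold values, their mean and the
population SD over folds. Paired comparisons between model variants use
the Wilcoxon signed-rank test: zero differences dropped, exact
sign-assignment distribution (dynamic programming over doubled ranks, so
average ranks from ties stay exact) for n ≤ 25, tie- and
continuity-corrected normal approximation above. Note the smallest
two-sided exact p for 5 paired folds is 0.0625: fold-level pairing alone
cannot reach p < 0.05, which is why the comparison tool also supports
pooling fold × metric pairs.

## Similarity analysis

To ask whether the interactome embeddings encode anything beyond molecular
similarity, protein pairs are scored by Smith–Waterman local alignment
(BLOSUM62, gap open 11 / extend 1, via Biopython; an externally computed
score table can be substituted) against the cosine of their PPI embeddings,
and compound pairs by fingerprint Jaccard against CCI-embedding cosine;
each scatter is summarized by Pearson r. On the synthetic benchmarks these
correlations are small (≈0.1–0.2), as expected: the generator plants
network communities and molecular features with only partial overlap.
`nearest_training_pair` ranks training pairs by the product of the two
per-side similarities, each normalized by its training-set maximum (the
two sides have incommensurable units); ties break by pair ID.

## Synthetic data

The generator emulates the statistical structure the method assumes, at a
scale where every property is testable in seconds:

* **Networks.** K protein and L compound communities (default 4 and 4);
  stochastic-block-model edges with p_in = 0.3 within and p_out = 0.02
  between communities. Edges receive integer channel scores at or above
  the conventional threshold, and a configurable fraction of sub-threshold
  decoy rows is added, so the emitted link tables exercise the filter and
  round-trip losslessly through the readers.
* **Molecular features.** Each protein carries the sequence motif of its
  *molecular* community with probability 0.9, inserted into an otherwise
  random 40–80-residue sequence; each compound's fingerprint is its
  molecular community's random template with 5% of bits flipped. Toy
  SMILES from a fixed list of simple valid structures accompany every
  compound for I/O and toolkit paths; they are not chemically meaningful.
* **Decoupling.** Each entity's molecular community equals its network
  community except for a `decouple_fraction` (default 0.5) reassigned
  independently. This is the crux: at 0 the modalities are redundant and
  fusion cannot help; at 0.5 each modality alone sees only part of the
  label signal, making the synergy comparison meaningful.
* **Labels.** A hidden K × L compatibility matrix C with ±1 entries sets
  pair propensity; a sampled pair (i, j) is positive with probability
  σ(α·C[net_i, net_j] + β·C[mol_i, mol_j] + bias), α = β = 2.5 by default,
  with the bias solved by bisection to hit the target positive rate (⅓,
  echoing the 1:2 design). Labels are therefore intrinsically noisy —
  conflicting community signals put pairs at coin-flip probability — which
  is deliberate: it caps attainable AUROC below 1 and exercises
  noise-robust training.

What the generator does **not** emulate: real confidence-score
distributions, realistic chemistry (fingerprints are templates, not ECFPs
of the toy SMILES), sequence homology families, hub-dominated degree
distributions, or dataset scale. Passing the synthetic studies shows the
pipeline recovers planted multi-modal signal under controlled conditions;
it does not certify performance on real STITCH/STRING-scale data.

## Study problem sizes

The bundled studies (`dtifuse.study`) use 60 proteins × 60 compounds, 600
labelled pairs, 32-dimensional embeddings (walk length 40, 10 walks,
window 5), a two-layer 16-filter CNN, latent dimension 32, and 80 training
epochs — sizes chosen so a full three-mode comparison trains in well under
a minute per seed on a single CPU while all three modes clear chance
comfortably. The qualitative conclusions (integrated ≥ both single
modalities with complementary signal; ablations α = 0 / β = 0 flip the
single-modality ordering) are stable across seeds at this scale.

## Known limitations

* The skip-gram trainer recomputes walk pair lists in memory; graphs with
  millions of nodes would need alias sampling and streaming, which are out
  of scope.
* DIAMOND itself is not re-implemented; the built-in local aligner is a
  stated substitute with the same scoring family, and external score
  tables plug in wherever a similarity callable is accepted.
* Hard-split training from the command line requires the per-entity group
  maps and is therefore exposed through the API (`split_hard` +
  `cross_validate`) rather than the `train` subcommand's fold-file path.
* Bit-exact ECFP reproduction across toolkits is not attempted; tests
  assert fingerprint properties, not specific hash values.
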