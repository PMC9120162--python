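# Methods

## Problem and pipeline

Protein–protein interaction (PPI) prediction is cast as binary
classification of protein pairs. Each protein is represented by its
residue contact network — a graph whose nodes are the amino-acid residues
of a 3D structure and whose edges connect residues with any inter-atomic
distance strictly below 6 Å — together with an `L×F` matrix of
per-residue node features. A shared (Siamese) encoder maps each protein
graph to a fixed-size vector; the concatenated pair vector is classified
by a small MLP with a sigmoid output.

## Structure parsing

Only `ATOM` records of the first `MODEL` are used; `HETATM` records
(waters, ligands) are excluded so that the derived sequence aligns
one-to-one with the graph nodes. For alternate locations only the first
encountered conformer of each atom name is kept. Chains are concatenated
in file order by default, with a flag to restrict to one chain; both
policies are deterministic, and the default reproduces single-chain
entries exactly. The sequence is derived from the ATOM records (never
SEQRES) so its length always equals the node count. MSE maps to M
(selenomethionine); other non-standard residue names map to 'X'.
Hydrogens, when present, participate in distance calculations; a
heavy-atom-only and a Cα-only mode are available as flags.

## Contact graphs

An edge requires minimum inter-atomic distance *strictly less than* the
cutoff; equality at 6.0 Å yields no edge. The stored adjacency is binary,
symmetric, zero-diagonal — a pure contact map. Self-loops are *not*
stored; the GCN layer adds `A + I_L` itself, so the same graph serves
both layer types. Sequence-adjacent residues get no special edges: at the
default cutoff a 3.8 Å backbone step always creates a contact anyway.

## Layers

* **GCN**: `H' = ReLU(D̂^{-1/2}(A+I)D̂^{-1/2} X W)`. The self-loop makes
  every augmented degree ≥ 1, so the normalization is always defined,
  including isolated nodes.
* **GAT**: single attention head. The raw score is the standard additive
  form `e_ij = LeakyReLU(a·[Wx_i ‖ Wx_j])` with negative slope 0.2; the
  neighborhood includes the node itself (mirroring the GCN's self-loop);
  the softmax is computed with per-row max subtraction for overflow
  safety. The output nonlinearity is LeakyReLU with slope 0.01. Slopes
  are configurable.
* **Mean pooling** produces the `(1, F')` graph-level vector; being a
  column mean it is permutation-invariant and length-independent.

Both layers are permutation-equivariant pure functions; each has an exact
hand-written backward pass validated against central finite differences
(tolerance 1e-5 at eps 1e-6) and against brute-force forward oracles
(dense normalized-adjacency product; per-node explicit softmax) to 1e-10.

## Model and training

Defaults: one GNN layer, `F' = 128`, protein representation 128 (so the
concatenated pair vector width 256 equals the first classifier layer),
classifier hidden sizes (256, 64), dropout 0.2 after every FC layer
(including the encoder's FC — the dropout placement after *every* FC
layer is taken literally), sigmoid output with the ≥ 0.5 decision rule,
MSE loss, Adam with learning rate 0.001 and standard moments. Epochs (50)
and batch size (32) are package choices, config-exposed. Initialization
is Glorot-uniform from the run seed; shuffling and dropout use a separate
generator derived from the same seed, so a run is reproducible
bit-for-bit given (seed, config, data). Encoder stacks of 2–3 layers
reuse the same layer contract back-to-back for the depth experiment
harness. Pairs are fed in the given order; an optional inference flag
averages both concatenation orders (the model is otherwise not symmetric
in the pair).

Training, like the layers, is pure NumPy: backpropagation through the
classifier, pooling and graph layers is written out explicitly, and Adam
updates a flat dict of parameter arrays. Checkpoints (HDF5: parameter
arrays + JSON config) round-trip bit-exactly.

## Evaluation

Threshold metrics (accuracy, Sn, Sp, Pr, F-score, MCC) are computed from
the confusion counts at the ≥ 0.5 rule; any 0/0 ratio is reported as 0
with a warning flag rather than raising, so cross-validation aggregation
stays total. AUROC uses the Mann–Whitney tie convention (half credit) and
AUPRC step interpolation, both via scikit-learn behind the module
surface; AUROC is cross-checked against exhaustive pair counting in
tests. k-fold cross-validation is stratified by label (disable by flag),
seeded, and reports mean ± sample sd over folds; an 80/20 stratified
hold-out utility is also provided. CV refolds over the full dataset by
default.

## Synthetic data

The generator emulates the pipeline's real inputs at desk scale:

* **Geometry**: self-avoiding random walks, consecutive residues exactly
  3.8 Å apart (the Cα–Cα virtual bond length), non-consecutive residues
  ≥ 3.0 Å apart, one CA pseudo-atom per residue (optional jittered
  side-chain atoms exercise the all-atom distance path). An optional
  compactness bias couples a protein's latent class to its contact
  density.
* **Features**: per-residue vectors = class motif + Gaussian noise. Class
  motifs are orthogonal unit directions scaled by `signal_strength`
  (default 2) with noise sd 1 — a mean-pooled separation many noise
  standard deviations wide at typical lengths, chosen so the benchmark
  probes the pipeline's correctness rather than the optimizer's limits.
* **Labels**: a pair interacts iff the two latent classes match,
  optionally flipped with `label_noise`. With two classes this is an
  XOR-type task on the pair — deliberately not linearly separable from
  concatenated protein vectors, so a trained classifier must use its
  hidden layers. Bayes accuracy is 1 at zero label noise; chance at zero
  signal.

Default study conditions: 80 proteins, lengths 30–60, feature dim 16,
400 pairs at a 1:1 positive:negative ratio (a skew option mirrors
imbalanced real datasets), seed 7.

What passing on this fixture does **not** show: real protein folds,
docking-style interface geometry, language-model embedding statistics, or
benchmark-scale generalization. The fixture validates the machinery
(formats, graph construction, layer math, training dynamics, metric
bookkeeping), not biological performance.

## Problem sizes and numerical choices

The test suite and the acceptance script run the benchmark at the study
conditions above (seconds per training run on one CPU); cross-validation
and the depth experiment use reduced epoch budgets (15 and 10) since they
check reproducibility and report completeness, not accuracy. Oracle
comparisons use 50–1000 random instances at small `L`. Tolerances: 1e-10
for layer-vs-oracle agreement, 1e-8 for permutation invariance of pooled
encodings, exact equality for determinism contracts.

## Known limitations

* Dense adjacency throughout — fine for desk-scale and typical single
  domains, quadratic in memory for very large complexes.
* Single-head GAT without edge features or multi-head averaging.
* No GPU path, early stopping, or learning-rate schedules.
* mmCIF input, NMR ensembles beyond the first model, and biological
  assemblies are out of scope; language-model embeddings are consumed
  precomputed through the store contract, never computed here. (Users
  producing their own store from a multi-layer language model should sum
  the per-layer outputs into one `L×F` matrix per protein.)
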