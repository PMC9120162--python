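# ppigraph

Structure-plus-sequence prediction of protein–protein interactions (PPI).
`ppigraph` builds **residue contact networks** from PDB coordinate files,
attaches per-residue node features, encodes each protein with a graph
neural network (GCN or GAT), and classifies protein *pairs* with a Siamese
two-hidden-layer classifier. It is written for structural bioinformaticians
who want a small, fully tested, dependency-light implementation of this
pipeline — every numerical component is NumPy with hand-written gradients
and is checked against independent brute-force oracles.

## The model

**Graph construction.** A protein with `L` residues becomes a graph
`G = (V, E)` with one node per residue; residues `i, j` are connected iff
any pair of atoms (one from each residue) lies at Euclidean distance
strictly below 6 Å.

**Node features** `X ∈ R^{L×F}`: one-hot amino-acid encoding (`F = 20`),
the seven Meiler physicochemical descriptors (`F = 7`), or precomputed
per-residue protein language-model embeddings loaded from a keyed HDF5
store (`F` = embedding width, e.g. 1024).

**GCN layer** (symmetric normalization, self-loops added inside the layer):

    H' = ReLU( D̂^{-1/2} (A + I_L) D̂^{-1/2} X W ),   D̂_ii = Σ_j (A + I_L)_ij

**GAT layer** (single head, self-inclusive neighborhood `N(i)`):

    e_ij = LeakyReLU( a · [W x_i ‖ W x_j] ),  α_ij = softmax_{j∈N(i)}(e_ij)
    H'_i = LeakyReLU( Σ_{j∈N(i)} α_ij W x_j )

**Pair classifier.** Global mean pooling gives a fixed-size `(1, F')`
protein vector regardless of length; an FC + LeakyReLU layer maps it to the
final protein representation. The two representations of a pair are
concatenated and passed through FC(256) → FC(64) → sigmoid, with dropout
0.2 after every FC layer; a pair is called interacting iff the output
probability is ≥ 0.5. Training minimizes the MSE loss with Adam
(learning rate 0.001). A graph-free baseline replaces the encoder by the
column-wise mean of the feature matrix.

Evaluation reports accuracy, sensitivity, specificity, precision, F-score,
MCC, AUROC and AUPRC, on a hold-out split or as mean ± sd over stratified
5-fold cross-validation.

A synthetic-data module generates desk-scale fixtures in the pipeline's
real input formats (PDB files, embedding store, pair list): self-avoiding
Cα walks with 3.8 Å steps and a planted, class-based interaction signal,
so the whole pipeline is exercisable and testable without any downloads.

## Worked example

```python
import ppigraph as pg
from ppigraph.synthetic_data import build_graphs

spec = pg.SyntheticSpec(n_proteins=40, length_range=(30, 60), feature_dim=16,
                        n_pairs=200, seed=7)
structures, features, dataset = pg.generate_pair_dataset(spec)
graphs = build_graphs(structures)
print("graph:", pg.graph_summary(graphs["p0000"]))

train_set, test_set = pg.train_test_split_pairs(dataset, 0.2, seed=7)
config = pg.ModelConfig(gnn_type="gat", epochs=30, seed=7)
params, history = pg.train(train_set, graphs, features, config)
print(f"training loss: {history.losses[0]:.4f} -> {history.losses[-1]:.4f}")
probs = pg.predict_dataset(test_set, graphs, features, params, config)
print(pg.evaluate_scores(probs, test_set.labels).as_dict())
```

Output:

```
graph: {'n_nodes': 60, 'n_edges': 113, 'degree_min': 1, 'degree_mean': 3.766..., 'degree_max': 8, 'n_isolated': 0}
training loss: 0.2414 -> 0.0001
{'acc': 1.0, 'Sn': 1.0, 'Sp': 1.0, 'Pr': 1.0, 'F_score': 1.0, 'MCC': 1.0, 'AUROC': 1.0, 'AUPRC': 1.0}
```

The first residue of `p0000` touches its chain neighbors and a few
fold-back contacts (degree 1–8 at the 6 Å cutoff). The planted class
signal (orthogonal feature motifs, strength 2 vs. noise sd 1) is strongly
learnable, so the GAT model separates interacting from non-interacting
pairs perfectly on the 40-pair hold-out set; the training loss falling
from 0.24 (chance level for MSE on balanced 0/1 labels) to ~1e-4 shows
the optimizer converged.

The same pipeline runs from the shell:

```sh
ppigraph simulate --seed 7 --out data/
ppigraph build-graphs data/pdbs --out graphs/
ppigraph train --pdb-dir data/pdbs --pairs data/pairs.tsv \
    --features embedding --embedding-store data/embeddings.h5 \
    --gnn-type gat --out-dir run/
ppigraph predict --pdb-dir data/pdbs --pairs data/pairs.tsv \
    --features embedding --embedding-store data/embeddings.h5 \
    --checkpoint run/checkpoint.h5 --out predictions.tsv
```

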