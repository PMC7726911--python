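# spatialgcn

Supervised inference of extracellular (and autocrine) ligand–receptor
interactions from spatial single-cell transcriptomics, using a graph
convolutional classifier over the cell neighborhood graph.

Imaging-based technologies such as seqFISH+ and MERFISH measure per-cell
transcript counts *and* cell positions. If a secreted ligand L signals to a
receptor R on neighboring cells, then R's expression in a cell should track
the summed L expression of that cell's spatial neighbors — a pattern that
correlation across cells alone cannot separate from shared cell-type
composition. `spatialgcn` frames the question as supervised binary
classification of ordered gene pairs.

## Model

Cells within a Euclidean distance threshold `d` (within the same field of
view) are connected in an adjacency matrix `A`. From `A` the package builds
the graph operators

- `L′ = D′^{-1/2}(A + I)D′^{-1/2}` — neighbors plus the cell itself
  ("autocrine+" model),
- `L_NN = I − D_N^{-1/2} A_N D_N^{-1/2}` with `A_N = D^{-1/2} A D^{-1/2}`
  ("exocrine" model),
- the identity `I` — a spatial-information-free "diagonal" control.

Each candidate pair (a, b) is encoded as an `n × 2` matrix `X` of per-cell
normalized expression (`expression_ij = count_ij / Σ_j count_ij × 10,000`).
The classifier is

```
Z₁ = elu(L X W₁ + b₁)          # n × 32
Z₂ = elu(L Z₁ W₂ + b₂)         # n × 32
h  = ReLU(dense₅₁₂(ReLU(flatten(Z₂))))
p  = sigmoid(w·h + b)          # P(interaction)
```

trained by Adam on summed binary cross-entropy, with early stopping on
validation accuracy (patience = half the epoch budget). Evaluation is
gene-exclusive 10-fold cross-validation: 90% of ligands and 90% of
receptors train, pairs straddling the split are removed, each positive gets
one matched negative `(L_a, R_x)` with `R_x` not a known partner of `L_a`,
and ROC / precision–recall curves are computed per ligand then aggregated
(mean, median, 40–60 percentile band). The forward pass, backpropagation,
and optimizer are implemented directly in NumPy.

Also included: a causal-direction task (rank `(L, R)` above the flipped
`(R, L)`), function assignment with a guilt-by-association baseline,
single-cell and spatial Pearson-correlation baselines, permutation controls
(shuffled neighborhoods, shuffled interaction lists), and a seeded
synthetic-data generator that plants autocrine/exocrine couplings with
known ground truth.

## Worked example

```python
from spatialgcn import (SimConfig, simulate, ExperimentConfig, TrainConfig,
                        run_experiment)

dataset = simulate(SimConfig(seed=1))          # 500 cells, 40 coupled pairs
cfg = ExperimentConfig(variant="autocrine_plus", k_folds=3,
                       train=TrainConfig(epochs=60), seed=101)
report = run_experiment(dataset, cfg)
print(f"mean AUROC {report.mean_auroc:.3f} over {report.n_curves} ligands")
```

```
mean AUROC 1.000 over 19 ligands
```

Each of the 19 held-out ligands contributes one ROC curve (its true
receptor versus a matched decoy); a mean AUROC of 1.0 means every planted
coupling outranked its decoy on this seed, while the same run with
`variant="diagonal"` (no spatial information) drops to 0.55 — the gap is
the part of the signal that is genuinely spatial. Pooled over five seeds
the spatial model averages around 0.9 (see the reproduction script). The
`examples/` directory has one short script per capability: simulation,
graph construction, training, direction, baselines, permutation controls,
and threshold selection.

A thin CLI mirrors the library:

```bash
spatialgcn simulate --out fixture/ --seed 1
spatialgcn train --data fixture/ --variant autocrine_plus --k-folds 3 --out run/
```

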