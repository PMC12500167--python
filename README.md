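# flowgen

Flow-based generative models for synthesizing single-cell RNA-seq
expression profiles, with a class-balancing generation protocol and a full
real-vs-synthetic evaluation suite.

## The problem

Annotated scRNA-seq datasets are almost always imbalanced: a few abundant
cell types dominate while rare populations contribute a handful of cells,
which degrades downstream cell-type classifiers exactly where they matter
most. `flowgen` addresses this by learning the expression distribution of
each cell type with a normalizing flow and generating synthetic cells for
the under-represented types, then quantifying how faithful the synthetic
cells are and how much they help classification.

## Models

Both models are normalizing flows: a chain of invertible maps
`h_0 = x, h_l = f_l(h_{l-1}), z = h_L` with `z ~ N(0, I_d)`, trained by
exact maximum likelihood through the change-of-variables formula
`log p(x) = log p_z(z) + sum_l log |det J_l|`.

- **MAF** (baseline): masked affine autoregressive transforms
  `z_i = (x_i - mu_i(x_{<i})) / sigma_i(x_{<i})` with a MADE-style masked
  conditioner, triangular Jacobian, `log|det J| = -sum_i log sigma_i`.
- **MoE flow**: a contextual feature-masking front end (a learnable soft
  interpolation of each gene toward the per-cell mean expression, applied
  on the density path only), ActNorm layers with exact log-determinant,
  and an affine coupling layer whose scale and shift come from a
  softmax-gated mixture of multi-head attention experts over the
  pass-through feature subset, followed by a MAF block.

Balancing follows the **Q3 rule**: the target size of every cell type is
the third quartile of the class-size distribution; a flow is fitted per
cell type that falls short, and exactly `Q3 - observed` cells are
generated for it.

Fidelity is measured by per-feature 1-D Wasserstein distance, correlation
discrepancy (mean absolute difference of Pearson gene-gene correlation
matrices), multi-scale RBF-kernel MMD, batch silhouette
(`1 - |mean silhouette|` over batch labels), RMSE for keyed interaction
tables, and random-forest cell-type classification
(precision/recall/F1/accuracy), all in a 50-component PCA space fitted on
the real training data only.

## Worked example

```python
import numpy as np
from flowgen import (FixtureConfig, simulate_fixture, preprocess_pipeline,
                     PreprocessParams, q3_plan, fit_per_type, generate_balanced,
                     TrainConfig, pc50_project, wasserstein_mean, mmd_rbf,
                     correlation_discrepancy)

data = simulate_fixture(FixtureConfig(seed=0))      # 2000 cells x 200 genes, 4 types
data = preprocess_pipeline(data, PreprocessParams(min_class=10, min_cells=10,
                                                  min_genes=10, n_hvg=100))
print("class counts:", data.class_counts())

plan = q3_plan(data.cell_types)
print("Q3 =", plan.q3_value, "targets:", plan.targets)

cfg = TrainConfig(hidden_features=64, learning_rate=0.01, n_iterations=40, seed=0)
models = fit_per_type(data, cfg, plan=plan)
synth = generate_balanced(models, plan, seed=0, gene_ids=data.matrix.gene_ids)
print("synthetic cells:", synth.n_cells, synth.class_counts())

_, real_p, (synth_p,) = pc50_project(data.X, [synth.X])
print(f"WD  = {wasserstein_mean(real_p, synth_p):.4f}")
print(f"CD  = {correlation_discrepancy(real_p, synth_p):.4f}")
print(f"MMD = {mmd_rbf(real_p, synth_p):.4f}")
```

prints

```
class counts: {'type0': 1302, 'type1': 465, 'type2': 175, 'type3': 58}
Q3 = 674 targets: {'type0': 0, 'type1': 209, 'type2': 499, 'type3': 616}
synthetic cells: 1324 {'type1': 209, 'type2': 499, 'type3': 616}
WD  = 0.1205
CD  = 0.0555
MMD = 0.0021
```

The simulated dataset has a ~20:1 spread between the largest and smallest
cell type; Q3 balancing raises every class to at least 674 cells.  The
discrepancy values compare the real cells against the synthetic pool in
PC space — small WD/CD/MMD mean the synthetic cells sit on the real
manifold (identical datasets give exactly 0 for each).

The same steps are available from the shell:

```bash
flowgen simulate --seed 0 --out data/raw
flowgen preprocess --input data/raw --min-cells 10 --min-genes 10 --hvg 100 --out data/prep
flowgen balance --input data/prep --hidden 64 --lr 0.01 --iters 40 --out-prefix data/synth
flowgen benchmark --input data/prep --model maf --hvg 100 --hidden 64 --lr 0.01 --iters 40 --out results/
```

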