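# pairatac

Probabilistic denoising and imputation of single-cell ATAC-seq through a
cell–peak bipartite graph model.

## The problem

Single-cell ATAC-seq measures chromatin accessibility one cell at a time,
but each cell yields only a few thousand fragments spread over hundreds of
thousands of peaks. The resulting cell-by-peak count matrix is extremely
sparse, and most zeros are technical dropout rather than closed chromatin.
This sparsity blurs cell-state boundaries and hides regulatory structure.
`pairatac` is for analysts who want denoised accessibility profiles,
low-dimensional cell and peak embeddings, and peak-level regulatory readouts
(modules, co-accessibility) from a raw count matrix — with a bundled
simulator and metric suite so every step can be validated on data with known
ground truth.

## The model

Cells `u_i` and peaks `v_j` are the two node sets of a bipartite graph with
an edge wherever the binarized matrix has `r_ij = 1(x_ij > 0)`. Trainable
ID embeddings `E⁽⁰⁾ ∈ R^{(N+M)×d}` are propagated K times by the
symmetric-normalized adjacency,

    E⁽ᵏ⁺¹⁾ = D^{-1/2} A D^{-1/2} E⁽ᵏ⁾,   A = [[0, R], [Rᵀ, 0]],

with no nonlinearity or feature transform, and the K+1 layers are averaged
into `Ē`. A variational layer places a diagonal Gaussian over every node:
`μ_i = ē_i`, `σ_i = softplus(MLP(μ_i))`, sampled as `z_i = μ_i + σ_i ⊙ ε`.

Two decoders reconstruct the data from the latent embeddings:

* **qualitative** — open probability `σ(z_i⁽ᶜ⁾ · z_j⁽ᵖ⁾)`, trained with a
  pairwise ranking (BPR) loss `−ln σ(h⁺ − h⁻)` against uniformly sampled
  closed peaks;
* **quantitative** — a Negative Binomial on counts with mean
  `μ′_ij = l_i · s_j · softplus(w·(z_i ⊙ z_j) + b)` (library size factor
  `l_i`, learnable peak factor `s_j`) and per-peak inverse-dispersion
  `θ_j`, so `Var = μ′ + μ′²/θ`.

The total objective `L = L_qual + α·L_quan + L_KL + β·‖E⁽⁰⁾‖²` (α = 1,
β = 1e-3, d = 64, K = 3, Adam at 5e-3 by default) is optimized with
analytically derived gradients in plain numpy; see `docs/methods.md` for
the exact term scaling and all numerical choices.

## Worked example

Simulate a 4-group block-structured dataset, hide half the signal, and
recover it:

```python
import numpy as np
from pairatac import TrainConfig, fit, simulate_block, apply_dropout, leiden_cluster
from pairatac.trainer import embed_cells, impute
from pairatac.metrics import ari, auroc_auprc

truth = simulate_block(n_cells=300, n_peaks=800, n_groups=4,
                       p_in=0.3, p_out=0.03, seed=100)
observed = apply_dropout(truth.counts, rate=0.5, seed=200)

model = fit(observed.counts, TrainConfig(n_layers=2, embedding_dim=16,
                                         epochs=200, seed=0))
clusters = leiden_cluster(embed_cells(model))
print(f"clustering ARI vs true groups: {ari(truth.labels, clusters):.3f}")

prob = impute(model, mode="probability")
ref = np.asarray(truth.counts.counts.todense())
masked = observed.mask
zeros = np.nonzero(ref == 0)
scores = np.concatenate([prob[masked], prob[zeros]])
labels = np.concatenate([np.ones(masked[0].size), np.zeros(zeros[0].size)])
auroc, auprc = auroc_auprc(scores, labels)
print(f"masked-entry recovery: auROC {auroc:.3f}, auPRC {auprc:.3f}")
```

Output:

```
clustering ARI vs true groups: 1.000
masked-entry recovery: auROC 0.789, auPRC 0.154
```

The ARI of 1.0 means Leiden clustering of the learned cell embeddings
recovers the four planted groups exactly despite 50% dropout. The auROC of
0.79 says that entries which were truly open but zeroed by dropout receive
systematically higher open probabilities than entries that were never open;
0.5 would be chance.

The same pipeline is available from the shell:

```bash
pair simulate --mode block --cells 300 --peaks 800 --groups 4 \
     --dropout 0.5 --seed 1 --out sim.h5
pair preprocess --in sim.h5 --format h5 --min-peaks-per-cell 10 \
     --min-cells-per-peak 3 --out clean.h5
pair fit --in clean.h5 --epochs 200 --seed 0 --out model.h5
pair embed --model model.h5 --out embeddings.tsv
pair impute --model model.h5 --mode probability --out imputed.h5
pair modules --model model.h5 --in clean.h5 --out-prefix mod
```

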