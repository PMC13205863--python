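# Methods

## Model

`pairatac` treats a QC-filtered scATAC-seq count matrix `X ∈ N^{N×M}`
(cells × peaks) as a bipartite graph: cell nodes, peak nodes, and an edge
wherever `x_ij > 0`. The assumptions are (i) the open/closed incidence
pattern carries the primary cell-state signal, (ii) count magnitude carries
complementary quantitative evidence that is over-dispersed and
depth-confounded, and (iii) technical dropout zeroes truly open entries at
random, so a model that shares information along the graph can recover
them.

**Encoder.** Trainable ID embeddings `E⁽⁰⁾` for all N+M nodes are
propagated by `Â = D^{-1/2} A D^{-1/2}` for K rounds and combined by a
uniform mean over layers 0..K. The propagation is deliberately linear (no
weight matrices, nonlinearities, or self-loops): on bipartite incidence
graphs this style of simplified message passing is more stable and equally
expressive after the layer readout, and including layer 0 in the mean keeps
each node's own information in the mix. Readout `mean` is the default;
`sum` and `concat` are available (`concat` only through the encoder
functions, since it changes the latent width).

**Variational layer.** Each node's posterior is
`N(μ_i, diag σ_i²)` with `μ_i` equal to the readout embedding and
`σ_i = softplus(MLP(μ_i))`. The MLP is one hidden layer of width d with
ReLU, then a linear map back to d; the output bias starts at −3 so σ starts
near `softplus(−3) ≈ 0.049`. Small initial noise keeps early ranking
gradients informative. One reparameterized sample per step is used during
training; all inference (embeddings, imputation) uses the deterministic
`z = μ`.

**Decoders.** The qualitative decoder scores pair compatibility by
`h_ij = z_i⁽ᶜ⁾·z_j⁽ᵖ⁾` and is trained by Bayesian personalized ranking:
for each observed edge, one closed peak of the same cell is drawn uniformly
and the loss `−ln σ(h⁺ − h⁻)` pushes open above closed. One negative per
edge per epoch, resampled every epoch. The quantitative decoder puts a
Negative Binomial on every count with mean
`μ′_ij = l_i s_j softplus(w·(z_i ⊙ z_j) + b)` and per-peak
inverse-dispersion `θ_j = softplus(u_j)`. The NB loss is evaluated over the
full peak vector of each batched cell — zeros included — because zeros are
informative under a count likelihood; `observed_only=True` restricts the
support to nonzero entries for users who prefer the sparser convention.

## Objective scaling

The training objective combines four terms:

    L = L_qual + α·L_quan + L_KL + β·L_reg,   α = 1, β = 1e-3.

Every term is expressed as an intensive (per-element) quantity: L_qual and
L_quan are means over their sampled supports, the node-summed KL is divided
by the N·M matrix entries whose reconstruction it regularizes, and L_reg is
the mean squared entry of `E⁽⁰⁾`. This choice matters. If the KL keeps its
raw node sum while the reconstruction losses are means, its gradient
dominates by three to four orders of magnitude and the posterior collapses
onto the prior (σ → 1, μ → 0), destroying the embeddings; a Frobenius-sum
l2 similarly cancels embedding growth at β = 1e-3. With per-element
scaling the published α and β keep their values and the balance between
components is independent of problem size. The standalone helper
`trainer.total_loss` assembles the objective from caller-supplied
components with the conventional Frobenius-norm penalty.

## Optimization

Adam (lr 5e-3, default betas) on all parameters: `E⁽⁰⁾`, the σ-MLP, and
the quantitative head (w, b, per-peak `s_raw`, `u_raw`; the latter two
start at `softplus⁻¹(1)` so peak factors and inverse-dispersions begin at
1). An epoch is one shuffled pass over the observed edges in chunks of
`edge_batch_size` (4096); each chunk is one gradient step combining the
ranking loss on the chunk, the NB loss on a cycled batch of
`cell_batch_size` (256) cells, the KL term and the l2 penalty. Default
budget is 300 epochs with early stopping on a 10-epoch moving average of
the total loss (patience 30). Gradients are derived analytically — the
model is a linear graph operator, a two-layer MLP, inner products and
smooth links, so backpropagation is short to write down — and the test
suite checks every parameter block against central finite differences.
All randomness (init, ε, negative sampling, batch order) derives from one
root seed through named `SeedSequence` streams, so runs are bitwise
reproducible; divergence (non-finite loss) aborts training and returns the
last finite state.

Numerical floors: μ and θ are clamped below at 1e-8 inside the NB
likelihood; the degree-normalized adjacency refuses degree-0 nodes
(callers run `qc_filter` first, defaults: ≥100 nonzero peaks per cell,
≥3 cells per peak, cells filtered before peaks in a single pass).

## Simulator

Two modes supply ground-truthed data.

**Block mode** plants cluster structure directly: cells and peaks are
split evenly into groups, entries open with probability `p_in` inside the
matched block and `p_out` outside, and open entries carry
`1 + Poisson(mean_count)` fragments — guaranteed nonzero, no
over-dispersion, so the pre-dropout matrix is an exact reference. Dropout
then zeroes each nonzero entry independently with the requested rate and
records the mask.

**Bulk-guided mode** draws diploid counts `c_ij ∼ Binomial(2, p_it)` with

    p_it = (n/2) · [ r_it (1 − q) + q/k ],

where `r_it` is the column-normalized bulk prevalence of peak i in type t,
`n` the per-cell fragment depth and `q` the fraction of reads redistributed
uniformly (non-specific cutting). The grouping of the mixture is chosen so
that the expected per-cell total `Σ_i 2 p_it = n(1−q) + nq = n` holds
exactly for every q, and the limits behave as intended: q = 0 is purely
bulk-driven, q = 1 purely uniform. `p_it` can exceed 1 for dominant peaks
at high depth; such entries are clamped to 1 with a logged count (the
conservation identity then becomes approximate). No external bulk profile
ships with the package: `synthetic_bulk_prevalence` builds a stand-in k×T
rate matrix from per-type Dirichlet draws whose concentration is tilted
(default ×6) on the type's own peak block — block-enriched like a
sorted-population bulk profile, but synthetic.

What the simulator does **not** emulate: batch effects, doublets,
fragment-level structure (TSS enrichment, fragment-size periodicity),
peak-width variation, and correlated (non-independent) dropout. Tests that
pass on these data therefore demonstrate correct mechanics and recoverable
signal under idealized sparsity, not performance on real tissue atlases.
In particular the default block dataset (300×800, 4 groups, p_in = 0.3,
p_out = 0.03, 50% dropout — the sizes used throughout the test suite to
keep runs short) is separable enough that a 16-dim truncated-SVD baseline
also clusters it perfectly; the block experiment validates recovery, not
superiority over linear methods.

## Metrics

Imputation: Pearson correlation summarized cell-wise and peak-wise
(zero-variance slices skipped with a logged count), auROC (tie-averaged
ranks) and auPRC (step interpolation) against the binarized reference.
Clustering: ARI; NMI normalized by the arithmetic mean of the entropies;
homogeneity `1 − H(C|K)/H(C)` and completeness `1 − H(K|C)/H(K)` with the
0/0 → 1 convention; V-measure `(1+β)hc/(βh+c)` with β = 1 by default.
Natural logarithms throughout; `0·log 0 = 0`.

Integration metrics operate on a Euclidean kNN graph (k = 15 default,
union-symmetrized). Cell-type ASW is `(silhouette + 1)/2`; batch ASW
averages `1 − |silhouette on batches|` within each cell-type group,
skipping groups with fewer than two batches. LISI uses the simple
k-neighbor category composition (not perplexity-weighted kernels): the
per-cell inverse Simpson index is medianed and rescaled to [0,1] by
`(B−x)/(B−1)` for labels (cLISI) and `(x−1)/(B−1)` for batches (iLISI).
kBET tests each sampled neighborhood's batch counts against the global
composition with a χ² goodness-of-fit test (dof = groups − 1), merging
batches smallest-first while any expected neighborhood count is below 1,
and reports the acceptance rate at α = 0.05. Graph connectivity averages
over labels the largest-connected-component fraction of the label-induced
subgraph; single-member labels count as connected.

Standard partition and silhouette scores delegate to scikit-learn behind
these interfaces; the test suite verifies them against an independent
brute-force contingency-table oracle over all 122² pairs of partitions of
six items into at most three blocks.

## Peak modules and co-accessibility

Peak embeddings feed a cosine kNN graph (k = 30 default) partitioned by
Leiden (resolution 1.0, seeded). Module activity of a cell is the fraction
of the module's peaks open in that cell, computed on the binarized
QC-filtered matrix — deliberately not the imputed one, so module scores
remain anchored to observed data. The cell-type heatmap matrix is the
per-type mean activity, z-scored per module across types with an `sd + eps`
denominator (eps = 1e-8). Co-accessibility of an anchor peak is the cosine
similarity of peak embeddings, ranked descending with the anchor excluded;
promoter-annotated hits are deduplicated to a gene shortlist at their best
rank (top 100 by default). Cosine was chosen to match the kNN graph
construction; Pearson on imputed profiles is a straightforward alternative
the API leaves to the caller.

## Known limitations

* The NB decoder has no zero-inflation component; datasets with excess
  structural zeros beyond NB dispersion are modeled only approximately.
* Dispersion is per-peak, not per-entry or hierarchical.
* Training is full-graph numpy on one CPU; it is comfortable at desk scale
  (hundreds to a few thousand cells) but not engineered for atlas-scale
  matrices.
* Batch covariates are not modeled explicitly; integration quality relies
  on the graph structure alone.
* The bulk-guided simulator's clamp at `p_it = 1` slightly biases total
  depth downward when dominant peaks meet high requested coverage.
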