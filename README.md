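# asap-topics

Topic models for large single-cell RNA-seq count matrices, made cheap by
working on randomly sorted pseudobulk aggregates (the ASAP pipeline).
Instead of factorizing a
gene-by-cell matrix with millions of columns, the pipeline first collapses
cells into at most `2^d` pseudobulk samples by sorting them down a
depth-`d` random-projection binary tree, fits a Bayesian topic model on
that small matrix, and then recovers per-cell topic proportions by a fast
per-cell regression against the learned dictionary. The package also
ships the copula-based benchmark simulator and the clustering-agreement
metrics (ARI / NMI / purity) used to evaluate it, plus a nearest-neighbour
deconvolution of bulk samples in topic space.

Intended users: computational biologists who want interpretable
grade-of-membership structure (topics ≈ gene programs) from large sparse
count matrices without feature selection, and a controlled synthetic
benchmark to stress-test such methods.

## Model

Counts follow a Gamma–Poisson (Poisson matrix factorization) model

    X_ij ~ Poisson(Σ_k β_ik θ_jk),   β_ik ~ Gamma(a₀, b₀),   θ_jk ~ Gamma(a₀, b₀),

with `i ∈ [D]` genes, `j` samples, `k ∈ [K]` topics. The three steps:

1. **Pseudobulk.** Project cells `Q = R X` with a Gaussian `R (d×D)`,
   orthogonalize `Q` by economy SVD and standardize rows; each cell's
   `d` signs form a binary code `B_kj = 1{Q̃_kj > 0}`, i.e. a leaf
   `l = Σ_k 2^(k−1) B_kj` of a perfect binary tree. Cells in a leaf are
   summed (`y_l = Σ_{j∈l} x_j`) and each pseudobulk column is scaled to
   a common library size of 10⁴.
2. **Factorization.** Mean-field variational inference on the pseudobulk
   matrix: multinomial responsibilities
   `z_ijk ∝ exp(E[ln β_ik] + E[ln θ_jk])` split each count over topics,
   giving conjugate updates
   `θ_jk ~ Gamma(a₀ + Σ_i y_ij z_ijk, b₀ + Σ_i E[β_ik])` and the mirror
   update for `β`; the ELBO is monotone under these coordinate updates.
3. **Cell regression.** With the dictionary fixed, each cell gets
   responsibilities
   `log ρ_jk = (Σ_i Y_ij E[ln β_ik]) / (Σ_i Y_ij) + E[ln θ_jk] + const`
   and the update `θ_jk ~ Gamma(a₀ + ρ_jk Σ_i Y_ij, b₀ + Σ_i E[β_ik])`,
   alternated a few times per cell. Cells are independent, so this
   streams in chunks of any size with bit-identical results.

Bulk samples are projected by the same regression after depth
normalization; their cell-type composition is estimated by counting
labelled cells among the k nearest neighbours in normalized topic space.

## Worked example

```python
import asap

# 13 simulated cell types, ~2,000 cells, depth 10,000 reads/cell
cfg = asap.BenchmarkConfig(
    cell_types=[f"type{t:02d}" for t in range(13)],
    cells_per_type=154, depth=10_000, rho=1.0, seed=7, D=1000,
)
X, labels = asap.make_benchmark(cfg)

res = asap.run_asap(X, depth=6, K=13, seed=7)   # the 3-step pipeline
print(res.pseudobulk.n_leaves)                  # 64  (= 2^6 occupied leaves)
clusters = asap.cluster_topics(res.cells.proportions, seed=0, resolution=0.25)
print(round(asap.adjusted_rand_index(clusters, labels), 3))   # 0.998
print(round(asap.purity(clusters, labels), 3))                # 0.999
```

With full signal (`rho = 1`) the recovered topic proportions cluster into
the 13 simulated types nearly perfectly (ARI 0.998); dialling `rho` down
toward 0.01 replaces type-specific variance with a shared multinomial
background and ARI decays to ≈ 0.

The same steps are available as a CLI:

```
asap simulate --types 13 --cells-per-type 154 --rho 1.0 --seed 7 --out sim/
asap pseudobulk --counts sim/counts.tsv -d 6 --seed 7 --out pb/
asap fit --pseudobulk pb/pseudobulk.tsv -k 13 --seed 7 --out fit/
asap project --counts sim/counts.tsv --model fit/model.npz --out proj/
asap evaluate --theta proj/theta.tsv --labels sim/labels.tsv \
              --resolution 0.25 --seed 0 --out eval/
# prints: ari=0.9978  nmi=0.9976  purity=0.9990
```

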