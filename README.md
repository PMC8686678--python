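# callr

Semi-supervised cell-type annotation for single-cell RNA-seq.

Given a gene × cell count matrix in which only a small fraction of cells
carry a type label — annotated by hand, or bootstrapped automatically from
marker-gene lists — `callr` infers the types of all remaining cells by
combining two sources of signal that are usually used separately:

* **supervised**: an L1-penalized multinomial logistic regression on the
  expression profiles, and
* **unsupervised**: a graph Laplacian over a mutual k-nearest-neighbor
  similarity graph of all cells, which penalizes assigning different types
  to transcriptionally similar cells.

It is aimed at analysts who have a dataset with partial annotations (or
good marker lists) and want per-cell type calls that exploit the geometry
of the whole dataset rather than the labeled subset alone.

## The model

For an expression matrix `X` (m genes × n cells, zero genes removed,
size-factor normalized), labeled subset `Z` with labels `g_i`, and K types,
the method seeks a one-hot K × n annotation matrix `U` minimizing

```
  - Σ_{i∈Z}  log P(g_i | x_i)  -  Σ_{i∈Z'} Σ_k u_ki log P(k | x_i)
  + λ₁ tr(U L Uᵀ)  +  λ₂ Σ_k ‖β_k‖₁
```

subject to `log[P(k|x)/P(K|x)] = α_k + β_kᵀ x` and one-hot columns, where
`L` is the Laplacian of the cell graph. The two blocks are optimized
alternately: **Step 1** updates `U` by projected gradient descent on the
product of probability simplices (`V ← Π(V + Δt(−V L + μ log P))`, with
`μ = 1/λ₁`) followed by thresholding each column to its nearest vertex;
**Step 2** refits the sparse regression on all cells with the current
labels. Labeled cells are clamped throughout. Defaults: `μ = 0.3`,
`Δt = 0.005`, `λ₂ = 0.004`, 17 mutual neighbors, adaptive Gaussian kernel.

The marker bootstrap (subcommand `select`) computes a TF-IDF transform
`T_ij = (X_ij/colsum_j)(1 + n/rowsum_i)`, zeroes entries below a per-gene
cutoff (0.25 × the 95th row percentile), sums the surviving weights over
each type's markers, and selects cells at or above the 85th score
percentile for **exactly one** type as that type's representatives.

## Worked example

```sh
callr simulate --seed 7 --n-cells 300 --m-genes 150 --k-types 4 --out-dir demo/
callr select   --expr demo/ --markers demo/markers.txt --out demo/picked.tsv
callr fit      --expr demo/ --labels demo/picked.tsv --seed 0 --out demo/pred.csv
callr eval     --pred demo/pred.csv --truth demo/truth.tsv
```

which prints (first the per-step summaries, then the evaluation):

```
wrote synthetic dataset to demo
selected 180 representatives across 4 types -> demo/picked.tsv
annotated 300 cells in 2 outer iteration(s); converged=True
{
  "ari": 0.9822632112222981,
  "nmi": 0.9743693533486925,
  "accuracy_all": 0.9933333333333333,
  "accuracy_unlabeled": 0.9833333333333333
}
```

`select` found 180 unambiguous representative cells from the marker lists;
`fit` propagated their labels to all 300 cells, agreeing with the planted
ground truth on 99.3% of cells (98.3% of the cells it had no label for),
with ARI 0.98 and NMI 0.97 against the true partition. The same pipeline is
available as library calls (`simulate`, `representatives_from_markers`,
`callr_fit`, `ari`/`nmi`/`accuracy`).

Input formats: 10X-style Matrix Market directories (`matrix.mtx` +
`genes.tsv` + `barcodes.tsv`) or dense CSV/TSV with gene rows; marker files
are plain text, one `type: gene, gene, ...` record per line; label files
are `cell_id<TAB>type`.

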