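# Methods

## Model

`callr` annotates the cells of a single scRNA-seq dataset transductively.
With `X` the m × n expression matrix (genes × cells), `Z` the labeled cell
subset, `K` the number of types visible in `Z`, and `U` a one-hot K × n
annotation matrix, the fit minimizes

    - Σ_{i∈Z}  log P(g_i | x_i)
    - Σ_{i∈Z'} Σ_k u_ki log P(k | x_i)
    + λ₁ tr(U L Uᵀ)
    + λ₂ Σ_{k<K} ‖β_k‖₁

where `P(k | x)` is a multinomial logistic model with intercepts α and
coefficients β (reference-class parametrization), and `L` is the Laplacian
of a cell similarity graph. The first term is the supervised likelihood of
the labeled cells; the second couples the label matrix to the classifier on
the unlabeled cells; the trace term is the weighted graph cut of the
assignment (it grows when similar cells receive different types); the L1
term keeps the gene coefficients sparse.

Preprocessing: genes with zero total expression are removed, then each cell
is divided by its library-size factor `s_j = colsum_j / median(colsums)`,
equalizing all column sums to the median library size. No log transform is
applied anywhere; both the graph and the regression operate on these
normalized counts. The exact size-factor estimator used by marker-scoring
pipelines elsewhere differs in detail; the median-ratio form used here is
the simplest deterministic read-depth adjustment and is the documented
contract.

## Cell graph

Nodes are cells; an edge joins i and j only when each lies within the
other's k = 17 nearest Euclidean neighbors (mutual k-NN, self excluded;
ties at the k-th distance break toward the lower cell index, which makes
the graph deterministic but — like any tie-break — not permutation-
equivariant on tie-prone integer data). Edge weights use a locally adaptive
Gaussian kernel with variance multiplier 1:

    ε_ij = (μ_i + μ_j + d_ij) / 3,     μ_i = mean distance of i to its k NN
    S_ij = exp(−d_ij² / (2 ε_ij²)) / (ε_ij √(2π))

**Laplacian normalization.** The default is the symmetric-normalized
Laplacian `L = I − D^(−1/2) S D^(−1/2)`. This is a deliberate choice with a
measurable reason: the kernel above returns *density* values, of order
1/(ε√2π) ≈ 10⁻² on size-normalized counts, so unnormalized degrees are
≈ 0.05 and the graph-cut gradient can never compete with the classifier
drift μ·log P (which reaches μ·|log 10⁻¹⁰| ≈ 7 at the probability floor).
With the unnormalized Laplacian the label update never flips a single cell
and the method degenerates to self-training. Degree normalization makes
neighbor votes O(1) — the scale at which the μ = 0.3 trade-off behaves as
intended — and is one of the standard spectral-clustering forms. The
unnormalized `L = D − S` (for which the cut identity
`tr(U L Uᵀ) = ½ Σ_ij S_ij ‖u_i − u_j‖²` is exact) remains available via
`laplacian: unnormalized`.

## Optimization

The objective is nonconvex jointly but convex in each block; the two blocks
are optimized alternately.

**Initialization.** The regression is fit on the labeled cells only and its
predictions (argmax of P) define U⁰; labeled columns are clamped to their
given one-hot values. A `init: random` variant exists for comparison.

**Step 1 (label update).** With the classifier fixed, the relaxed problem
over the product of probability simplices is solved by projected gradient
descent:

    V ← Π_simplex( V + Δt (−V L + μ log P) ),    μ = 1/λ₁, Δt = 0.005

followed by thresholding every column to its nearest simplex vertex (the
argmax — the simplex projection preserves coordinate order, so the
composition of the two projections is the argmax vertex). The iterate stays
*continuous* between steps, in the diffuse-then-threshold spirit of
graph-MBO schemes. Thresholding every step instead would pin the iterate to
its starting vertex: one step of size Δt moves a coordinate by at most
Δt·‖gradient‖ ≈ 0.03, never enough to cross the gap of 1 between one-hot
coordinates. Probabilities are clamped below at 10⁻¹⁰ before logarithms.

The inner loop stops when the one-hot readout has not changed for 1000
consecutive iterations, or the continuous iterate moves less than 10⁻⁷ in
max-norm, with a cap of 4000 iterations. The patience window must exceed
the relaxation time constant 1/Δt = 200 iterations; shorter windows stop
before any label can flip.

**Step 2 (classifier update).** With the labels fixed, the problem is an
L1-penalized multinomial logistic regression on *all* cells, fit with the
saga solver; the penalty follows the per-observation loss scaling
`(1/n)·loglik + λ₂‖β‖₁` (i.e. `C = 1/(n λ₂)`), with λ₂ = 0.004. The solver
uses the symmetric softmax parametrization internally; predicted
probabilities are the exposed surface and `intercepts`/`coefficients`
report the reference-class differences. Features are not standardized by
default (size-factor normalization is the only scaling); a switch exists.

**Outer loop.** Step 1 and Step 2 alternate until the Step-1 output repeats
exactly between consecutive rounds (cap 50). The refit on all cells runs in
every round, including the first — so the self-training effect of
re-estimating the classifier from the propagated labels always takes
place — and labeled cells keep their given types in the output.

The tracked quantity `−μ Σ_{i∈Z'} u_i·log P_i + tr(U L Uᵀ)` is reported per
round for diagnostics; the thresholding step makes monotone descent not
guaranteed. The spectral norm of L is estimated once per fit and logged
against the step-size bound Δt ≤ 1/‖L‖ (informational, not enforced).

## Marker-based bootstrap

When no labels are given, representatives are selected from marker lists:
TF-IDF transform `T_ij = (X_ij / colsum_j)(1 + n / rowsum_i)` of the
normalized matrix; per-gene cutoff `C_i = 0.25·q_i` with `q_i` the 95th
percentile of gene i's row (computed over all n cells, zeros included,
linear interpolation between order statistics); entries below `C_i` zeroed;
marker score `S_cj = Σ_{g∈G_c} T_gj`; cells at or above the 85th percentile
of `S_c·` for **exactly one** type become representatives (ties at the
threshold count as selected; a cell clearing two thresholds is dropped even
if one score dominates). Marker genes absent from the matrix are dropped
with a warning; a type losing all markers, or ending with zero
representatives, is an error (droppable via `on_empty_type="drop"`).

Note that the selection size is *not* monotone in the percentile over its
whole range: at low percentiles the thresholds drop into the noise floor,
many cells clear several thresholds at once, and the uniqueness filter
removes them.

## Evaluation metrics

ARI and NMI are computed from the contingency table:
`RI = Σ C(n_ij,2)/C(n,2)`, `ARI = (RI − E[RI])/(max RI − E[RI])` under the
permutation model, and `NMI = 2 I/(H_A + H_B)` with natural logarithms (the
normalization cancels the base). Degenerate conventions: identical trivial
partitions score 1 (else 0) for ARI; two single-cluster partitions score 1
for NMI. Accuracy is the exact-match fraction, by default over the
unlabeled cells only.

## Synthetic data

The generator draws counts from a negative binomial with mean
`baseline_mean · exp(log_fold_change · 1[g marks t])` scaled by a per-cell
log-normal library factor (σ = 0.3); dispersion θ = 0.5 (variance
μ + μ²/θ), the strongly overdispersed regime typical of droplet data — at
θ = 2 the benchmark becomes trivially separable and the semi-supervised
comparison degenerates. Defaults: 600 cells, 200 genes, 4 equiprobable
types, 10 markers per type, fold change e² ≈ 7.4, labeled ratio r = 0.05
revealed stratified by type (at least one cell per type, largest-remainder
allocation of ⌈r·n⌉ slots).

What it emulates: overdispersed counts, read-depth variation, marker-driven
type structure, sparse labels. What it does not: batch effects, doublets,
ambient RNA, rare types, correlated gene modules, dropout beyond what the
NB provides. Passing benchmarks therefore demonstrate correct mechanics and
qualitative behavior (gain over the supervised-only start, stability in r
and μ), not performance claims on real tissue.

## Known limitations

* The Step-1 scheme is a heuristic: on small enumerable instances it lands
  within 5% of the true optimum ≳ 90% of the time when the classifier is
  consistent with the graph geometry (the method's operating assumption),
  dropping to ~80% when the two are made deliberately inconsistent.
* Types absent from the labeled set cannot be discovered; K is fixed by Z.
* Distances use all genes with no dimensionality reduction; dense in-memory
  matrices bound the practical dataset size (tens of thousands of cells).
* The kernel is a single adaptive Gaussian; multi-kernel similarity fusion
  is out of scope.
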