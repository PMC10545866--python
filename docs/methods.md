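# Methods

## Model

The package predicts drug–disease associations by separating two
structured third-order tensors into a low-rank part and a sparse
residual.  The underlying assumptions are:

* *similar drugs treat similar diseases*: the true association
  structure is approximately low-rank jointly with the similarity
  matrices stacked along the third mode;
* *errors are sparse*: noise in similarity estimates and spurious or
  missing associations affect a minority of entries, so an L1-penalised
  residual captures them;
* *scores are probabilities of a sort*: meaningful predictions lie in
  [0, 1], enforced as a hard box constraint on the low-rank part.

The decomposition solves

    min_{X,E}  lambda * ||E||_1 + ||X||_{w,Sp}^p
    s.t.       M = X + E,  0 <= X <= 1,

with the weighted tensor Schatten p-norm
`||X||_{w,Sp} = (sum_i sum_j w_j * sigma_j(Xbar_i)^p)^(1/p)` taken over
the singular values of the Fourier-domain frontal slices (the t-SVD
view of a third-order tensor: circular convolution along tubes becomes
a slicewise matrix product after a DFT along mode 3).  With `p = 1`
and unit weights the norm is the tensor nuclear norm and the model is
classical tensor robust PCA; `p < 1` and ascending weights shrink the
small (noise) singular values proportionally harder.

## Optimisation

An inexact augmented Lagrangian loop from `X = E = L = 0`:

1. `E <- soft_threshold(M + L/mu - X, lambda/mu)` — elementwise L1 prox.
2. `X <- box_project(prox_{w,Sp}(M + L/mu - E, 1/mu))` — per Fourier
   slice, descending singular values are shrunk by scalar generalized
   soft-thresholding (GST) with per-value weight `w_i / mu`, weights
   ascending; the result is clamped to [0, 1].
3. `L <- L + mu * (M - X - E)`; `mu <- min(rho * mu, mu_max)`.

GST solves `min_d 0.5*(d - s)^2 + w*|d|^p` exactly: zero below the
closed-form threshold `tau = (2w(1-p))^(1/(2-p)) + wp(2w(1-p))^((p-1)/(2-p))`
(limit `tau = w` at `p = 1`), otherwise the larger stationary root via
fixed-point iteration started at `|s|` (cap 100 steps, tolerance 1e-12;
the start point lies in the basin of the larger root, and the boundary
`|s| = tau` is assigned to the zero branch).  Only Fourier slices
`0 .. n3//2` are processed; the rest are filled by conjugate mirroring
so the inverse transform is exactly real rather than real-by-rounding.

**Stopping.**  The loop stops when the relative iterate change
`f_k = ||X_{k+1} - X_k|| / ||X_k||` satisfies `f_k <= tol1` (1e-3) and
`|f_{k+1} - f_k| / max(1, |f_k|) <= tol2` (1e-4), *and* the constraint
is met to `||M - X - E|| <= 1e-6 * ||M||`.  The feasibility clause is
necessary: starting from zero with `mu_0 = 1e-4`, the iterate change is
trivially zero during the transient in which every singular value is
below the shrinkage threshold, and the two f-based inequalities alone
would fire immediately.  A zero previous iterate uses denominator 1,
so an exactly zero input converges at the first check.

**Determinism.**  The solver contains no randomness; LAPACK returns
singular values in non-increasing order and ties keep index order, so
identical inputs give bitwise identical results.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `lam` | `1/sqrt(n3 * max(n1, n2))` | sparsity weight; see below |
| `p` | 0.9 | Schatten exponent; 1 = convex nuclear-norm shrinkage |
| `rho`, `mu0`, `mu_max` | 1.1, 1e-4, 1e10 | penalty schedule |
| `tol1`, `tol2`, `feas_tol` | 1e-3, 1e-4, 1e-6 | stopping rule |
| `max_iter` | 500 | iteration cap |
| `weight_levels` | (1, 2, 4) | three-tier singular-value weights |
| `weight_fractions` | (0.1, 0.2) | spectral-energy split points |
| `k` (WKNN) | 30 | neighbour count (capped by eligible neighbours) |
| `alpha` (WKNN) | 0.95 | geometric decay over the neighbour ranking |

The `lam` default is the canonical tensor-robust-PCA scaling.  We
measured the alternative `1/(5*sqrt(n1*n2*n3))` on the planted-recovery
benchmark: at that magnitude the L1 term is so cheap that the trivial
solution `E = M, X = 0` dominates and the ALM collapses to it (relative
recovery error 1.0), whereas `1/sqrt(n3*max(n1,n2))` recovers the
planted tensor to 1e-4.  `lam` remains configurable for datasets whose
corruption rate differs from the ~5% regime.

**Adaptive weights.**  For each Fourier slice of the *input* tensor,
`u_j` (`v_j`) is the smallest number of leading singular values holding
at least 10% (20%) of the slice's singular-value mass; the rounded
slice averages `U <= V` split the weight vector into tiers 1 / 2 / 4.
Weights are computed once, before iterating, from the transformed
input: the prox acts on Fourier-slice spectra, so that is the scale on
which "leading" is meaningful.  All-zero slices contribute
`u_j = v_j = 1`; `U`, `V` are clamped to `[1, min(n1, n2)]`.

**Convention note.**  The tensor nuclear norm here sums the nuclear
norms of *all* `n3` Fourier slices without a `1/n3` factor; some of the
literature includes the factor.  The choice only rescales `tau` against
`lam` and is consistent throughout the package.

## WKNN details

* "Known" means at least one validated association in the *original*
  binary matrix; neighbour profiles are the original binary columns/rows,
  never recursively updated ones.
* The query is excluded from its own neighbour pool; ties in similarity
  break toward the lower index.  Fewer than `k` eligible neighbours
  means all are used.
* The normaliser `Q` sums the plain similarities of the selected
  neighbours (not the decayed ones), so the decay genuinely discounts
  far neighbours instead of being normalised away.
* If all neighbour similarities are zero the profile is set to zeros
  and a warning is logged.

## Evaluation protocol

Positives are split into 10 near-equal random folds (seeded).  For each
fold, the held-out positives are zeroed in the training matrix *before*
WKNN — densification would otherwise leak them into neighbouring
profiles.  Candidates are all cells that were not training positives;
negatives are never subsampled.  AUC is the normalised Mann–Whitney U
statistic with midrank ties; AUPR is step-integrated average precision;
"precision" is R-precision (precision at a cutoff equal to the number
of held-out positives; the cutoff is configurable).  The pooled ranking
over all candidate cells is the default; a per-drug ranking (metrics per
drug column, averaged over drugs holding test positives) is available as
an option since both conventions appear in this literature.  Top-n
validation counts rank each drug's non-training diseases with stable
tie-breaking.

## Synthetic data

`generate_dataset` draws non-negative latent factors B (diseases ×
rank) and C (drugs × rank), forms the propensity P = BCᵀ rescaled to
[0, 1], and places the 1s of A at the top `density·n·m` propensity
cells (top-k thresholding, so the positive count — and hence fold
sizes — is exact and reproducible).  Similarity matrices are cosine
similarities of the factor rows plus independent symmetric Gaussian
noise, clipped to [0, 1] with unit diagonal: associations and
similarities share the same latent cause, which is exactly the premise
the method needs, so recovery is expected and its failure would indicate
a defect.  Defaults (80 diseases × 120 drugs, rank 6, density 0.02,
noise 0.1) are a desk-scale rendition of curated drug-indication
benchmarks, which have a few hundred entities and ≈1–2% density.

What the generator does **not** emulate: block/community structure and
heavy-tailed degree distributions of real indication data, similarity
matrices estimated from heterogeneous sources with structured (not
i.i.d.) disagreement, and annotation biases (well-studied drugs having
more recorded indications).  Passing tests therefore demonstrate
correctness of the machinery and recoverability of planted low-rank
signal — not clinical performance.

`generate_lowrank_sparse_tensor` plants an exact low-tubal-rank tensor
(t-product of two factor tensors; non-negative factors and pure
rescaling in box mode, so the per-slice Fourier rank bound is preserved)
plus ±magnitude corruption on a Bernoulli support.

## Problem sizes and runtime

Test and acceptance runs use the generator defaults (80×120, five drug
and two disease similarity views), for which one end-to-end prediction
takes a few seconds and a full 10-fold cross-validation about a minute
on one CPU; the planted-tensor solver benchmarks use 20×15×4 and
30×30×4 instances.  These sizes exercise every code path (multi-slice
tensors, adaptive weights, both pipeline views) while keeping the whole
suite fast.

## Known limitations

* With `p = 0.9` and adaptive weights on small tensors, the 10%/20%
  energy fractions can assign weight 4 to informative singular values
  (small spectra concentrate energy in the first value), leaving a few
  percent of clean signal in E — measured at 6–8% relative error on
  clean rank-3 20×15×4 inputs, versus ~0.01% for `p = 1` with uniform
  weights.  On larger tensors the tiers resolve better.
* The ALM is an inexact first-order scheme for a non-convex objective
  (`p < 1`); it is deterministic and empirically stable, but there is
  no global-optimality guarantee.
* Similarity matrices are consumed, not computed: chemical,
  ATC, side-effect, interaction-profile, target, phenotype and ontology
  similarities must be supplied (or simulated).  Only Jaccard similarity
  from binary profiles is provided as a utility.
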