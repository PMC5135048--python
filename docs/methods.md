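# Methods

## Model

Semi-supervised component analysis (SCA) estimates a linear map
`y = Aᵀx` for feature vectors `x ∈ ℝᵐ` from a training matrix with rows
split into `n_l` labeled and `n_u` unlabeled samples (`n = n_l + n_u`,
unlabeled ratio `β = n_u/n`).  All second-order structure is expressed in
the graph-embedding framework as quadratic forms `XᵀLX` over n×n sample
Laplacians:

- total: `L_t = (1/n)(I − eeᵀ/n)`, so `XᵀL_tX = Σ` (covariance about the
  grand mean);
- within-class: `L_w = (1/n_l)·blockdiag_q(I − e_q e_qᵀ/n_q)` over the
  labeled class blocks, zero elsewhere, so `XᵀL_wX = Σ_w` (within-class
  covariance of the labeled samples);
- semi-supervised: `L = L_t − [(n_l/n)L_w 0; 0 0]`.

SCA maximizes `tr(AᵀXLXᵀA)` subject to
`(α n_u/n)AᵀA + (n_l/n)AᵀΣ_wA = I` and is solved as the generalized
symmetric eigenproblem `XLXᵀA = {(α n_u/n)I + (n_l/n)Σ_w}AΛ`.
The objective decomposes as `XLXᵀ = (1/n)(S_b + S_u)` with `S_b` the
between-class scatter of labeled class means and `S_u` the total scatter
of unlabeled samples, both about the grand mean; both terms are PSD, so
the spectrum is non-negative.  At `n_u = 0` the problem is exactly LDA's
`Σ_b A = Σ_w A Λ`; at `n_l = 0` it is PCA up to the constraint rescaling
`A ← A/√α`, which leaves all distance-based downstream decisions
unchanged.

The model assumes class-conditional structure that second-order
statistics can separate (roughly: classes differing in their means, with
comparable within-class dispersion) and that unlabeled samples are drawn
from the same mixture as labeled ones.  It does not model label noise:
labels hidden by the evaluation protocol are missing at random by
construction, which is the regime the β-sweep emulates.

## Parameters

- `alpha` (constraint scaling, variance units): balances the isotropic
  `AᵀA` term against the within-scatter term.  Default AUTO =
  `tr(Σ)/m`, the average per-dimension variance of the **full** training
  set (labeled + unlabeled).  Because α then scales as the features do,
  the fitted transformation is globally scale-invariant: rescaling all
  features by `c` rescales `A` by `1/c` and leaves `y = Aᵀx` fixed.
  In the dual, where m is the implicit feature-space dimension, AUTO uses
  `tr(K_c)/(n·rank(K_c))` with `K_c` the doubly-centered Gram matrix:
  `tr(K_c)/n` equals the feature-space variance trace and the numerical
  rank stands in for the dimensionality, preserving the
  average-per-dimension-variance meaning.  For a full-rank linear kernel
  this coincides with the primal rule, which keeps primal–dual
  equivalence exact under AUTO.
- `n_components`: default full rank — every eigenpair the solver returns
  — matching an evaluation protocol that compares methods at equal
  dimensionality.  `rank_policy` records the request, the count of
  eigenvalues above `1e-10·λ_max`, LDA's informative cap `k−1`, and any
  ridge applied.
- kernels: linear, RBF (`exp(−γ‖x−z‖²)`, γ > 0, default `1/m`),
  polynomial (`(γ xᵀz + c₀)^d`).  The Gram matrix is used **raw**; the
  Laplacians center internally, so no double-centering is applied (a
  test pins this).
- similarity graph (LPP/SDA): symmetric k-NN (union rule: an edge if
  either endpoint selects the other), heat-kernel weights
  `exp(−d²/t)`, no self-loops, neighbor ties broken by sample index.
  Defaults `k = 5`, `t = 1`; `t` and SDA's regularizer are meant to be
  tuned on the `2⁻¹⁵…2¹⁵` grid by stratified 5-fold CV, as the
  evaluation module does.

## Evaluation protocols

`remove_labels` hides `round(β·n)` labels (half-up rounding) chosen
uniformly — not stratified, though a redraw guard (up to 100 draws)
keeps every class represented whenever β < 1, since the within-class
Laplacian needs each labeled class nonempty.  `beta_sweep` refits the
transformer per draw and classifies with *all* ground-truth training
labels in the transformed space, so only the transformer — never the
classifier — is deprived of labels; β = 0 and β = 1 are deterministic and
evaluated once (std 0).  Supervised methods (LDA/KDA) are fitted on the
labeled subset at intermediate β and recorded as NaN at β = 1 rather
than failing the sweep.  `stratified_kfold_eval` nests label removal
inside stratified folds.  All randomness derives from one master seed
via `numpy.random.SeedSequence` spawning (per class in the generators;
per β, repetition and fold in the protocols), so every reported number
is bit-reproducible; seeds below 2³¹ are passed to scikit-learn's fold
shuffler.

## Numerical choices

- Generalized eigenproblems are solved with `scipy.linalg.eigh(S, M)`
  (both sides symmetric, M PSD).  If M's smallest eigenvalue is below
  `1e-12·tr(M)/m`, a ridge `1e-8·tr(M)/m·I` is added and recorded in
  `rank_policy["jitter"]`.  The ridge magnitude caps the condition
  number near 1e8 — the largest at which float64 can still certify the
  normalization `VᵀMV = I` to ~1e-8; a much smaller ridge lets
  eigenvectors in M's near-null space grow until the constraint product
  itself loses six or more digits.  After solving, the eigenvector block
  is re-orthonormalized against M via a Cholesky correction (this mixes
  only near-degenerate columns, preserving eigen-residuals).
- If M has non-positive trace the solver raises
  `SingularConstraintError`.  The primal fits (`fit_sca`, `fit_lda`)
  additionally refuse outright when m > n: the problem is then
  inherently ill-posed and the dual formulation is the intended route —
  this refusal is deterministic rather than dependent on a numerical
  rank estimate.
- Eigenvalues are sorted by a stable sort (descending; ascending for
  LPP), and each eigenvector's sign is fixed so its largest-magnitude
  entry is positive, making output reproducible across solver backends.
- `transform` applies `y = Aᵀx` without mean subtraction: fitting
  centers implicitly through the Laplacians, and the nearest-neighbor /
  nearest-mean decisions are translation-invariant only through the
  optional `center` flag (default off, recorded in the model).
- Gram matrices with eigenvalues below `−1e-8·λ_max` are clipped to PSD
  with a warning.
- Classifier distance computations saturate to `inf` on overflow
  (relevant only for absurd hyperparameters met during grid search);
  the protocols treat non-finite transformed features as a failed fit,
  recorded per cell.

## Synthetic data

`gaussian_mixture` draws class-conditional Gaussians with configurable
means and shared or per-class covariances — the statistical structure
the method's second-order machinery assumes, standing in for extracted
image-feature tables.  `illposed_features` embeds class-structured
points from a low-dimensional latent space into an ambient dimension
larger than the sample count via a random linear map plus isotropic
noise (default noise 0.01), emulating deep-descriptor tables where
m ≫ n.  What these generators do **not** emulate: heavy-tailed or
multimodal within-class distributions, label noise, class imbalance
beyond what the caller configures, and feature correlations of real
descriptors.  Passing tests therefore certify the algebra, contracts and
protocols — not classification performance on real tissue images.

Benchmark sizes used by the test suite and `scripts/acceptance.py`
(tens to low hundreds of samples, m ≤ 8 primal / 4096 dual) were chosen
as the smallest scales at which every identity, limiting case and
protocol property is exercised with well-conditioned statistics.

## Known limitations

- Laplacians are dense n×n; practical up to a few tens of thousands of
  samples.  The low-rank-plus-block structure of L is not exploited.
- The dual model stores the full training matrix, since out-of-sample
  transformation needs kernel evaluations against every training point.
- `remove_labels` guards against class extinction by redrawing, which
  at extreme β slightly biases the hidden set away from small classes;
  a stratified removal option exists but is off by default to keep the
  protocol's plain uniform split.
- Grid search re-tunes hyperparameters once per dataset/β setting, not
  per repetition.
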