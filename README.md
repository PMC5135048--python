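# scakit — semi-supervised component analysis

`scakit` is a dimensionality-reduction library for feature tables with
partially observed class labels, built around **semi-supervised component
analysis (SCA)**: a single generalized eigenproblem that couples principal
component analysis (PCA) and linear discriminant analysis (LDA) through
the graph-embedding view of multivariate analysis.  It is aimed at
image-classification pipelines — e.g. tissue-image analysis, where
features such as GIST or CNN descriptors are cheap but reliable class
labels are scarce — but applies to any numeric feature matrix.

## The method

Write a training set as rows of `X` (n samples, m dimensions), of which
`n_l` carry a class label and `n_u = n − n_l` do not (`β = n_u/n` is the
unlabeled ratio).  In the graph-embedding framework every covariance-like
matrix is a quadratic form `XᵀLX` over an n×n sample Laplacian `L`:
the total Laplacian `L_t = (1/n)(I − eeᵀ/n)` yields the covariance Σ, and
a block-diagonal within-class Laplacian `L_w` yields the within-class
covariance Σ_w of the labeled samples.  SCA maximizes

    tr(Aᵀ X L Xᵀ A),   L = L_t − [(n_l/n)·L_w  0; 0  0]

subject to the mixed constraint

    (α·n_u/n)·AᵀA + (n_l/n)·AᵀΣ_wA = I,

solved as the generalized symmetric eigenproblem
`XLXᵀA = {(α·n_u/n)I + (n_l/n)Σ_w}AΛ`.  The objective equals
`(1/n)(S_b + S_u)` — between-class scatter of the labeled samples plus
total scatter of the unlabeled ones, both about the grand mean — so the
method discriminates where labels exist and preserves variance where they
don't.  With every sample labeled it reduces to LDA; with none, to PCA.
The scaling α balances the two constraint terms and defaults to
`tr(Σ)/m` (average per-dimension variance), which makes the fitted
transformation invariant to a global rescaling of the features.

For ill-posed problems (m > n, e.g. 4096-dimensional CNN descriptors of a
few hundred images) the dual (kernel) form solves
`KLKB = {(α·n_u/n)K + (n_l/n)K L_w K}BΛ` over the raw Gram matrix K, with
linear, RBF and polynomial kernels.

The package also provides the standard comparators in primal and dual
form — PCA, LDA, locality preserving projections (LPP) and
semi-supervised discriminant analysis (SDA) — the 1-nearest-neighbor and
nearest-mean evaluation classifiers, and the evaluation protocols
(β-sweep with repeated random label removal, stratified k-fold CV,
power-of-two grid search) used to benchmark them, plus synthetic data
generators so everything runs without downloads.

## Worked example

```python
import numpy as np
from scakit import (MethodSpec, beta_sweep, fit_sca, gaussian_mixture,
                    remove_labels, transform)

# two tissue-like classes, 6-dimensional features, 60 train / 30 test each
mu = np.array([1.5, 0, 0, 0, 0, 0])
X_train, y_train = gaussian_mixture([60, 60], [mu, -mu], np.eye(6), seed=0)
X_test, y_test = gaussian_mixture([30, 30], [mu, -mu], np.eye(6), seed=1)

# hide 70% of the training labels, fit SCA with automatic scaling
partial = remove_labels(y_train, beta=0.7, seed=0)
model = fit_sca(X_train, partial)
print(f"alpha = {model.alpha:.4f}, leading eigenvalues = "
      f"{np.round(model.eigenvalues[:3], 4)}")

# recognition rate vs unlabeled ratio, 10 random label removals per beta
for name in ("sca", "pca", "lda"):
    res = beta_sweep(X_train, y_train, X_test, y_test, MethodSpec(name),
                     beta_grid=[0.0, 0.5, 1.0], repetitions=10, seed=0)
    print(res.summary().to_string(index=False))
```

prints

```
alpha = 1.3343, leading eigenvalues = [2.3545 0.8942 0.6577]
method classifier  beta  mean_rate  std_rate
   sca         nn   0.0   0.933333     0.000
   sca         nn   0.5   0.918333     0.005
   sca         nn   1.0   0.916667     0.000
method classifier  beta  mean_rate  std_rate
   pca         nn   0.0   0.916667       0.0
   pca         nn   0.5   0.916667       0.0
   pca         nn   1.0   0.916667       0.0
method classifier  beta  mean_rate  std_rate
   lda         nn   0.0   0.933333  0.000000
   lda         nn   0.5   0.923333  0.011055
   lda         nn   1.0        NaN       NaN
```

`alpha` is the automatic scaling `tr(Σ)/m`; the eigenvalues are the
leading generalized eigenvalues of the SCA problem.  Each table row is
the mean fraction of correctly classified test samples (1-NN in the
transformed space, classified with *all* ground-truth training labels)
over ten random label removals at that β, ± its standard deviation.
Endpoints are deterministic (std 0).  SCA matches LDA at β = 0 and PCA at
β = 1, and interpolates in between; supervised LDA has no fit at β = 1,
recorded as NaN rather than an error.

The same workflows are available from the shell:

```bash
scakit simulate --n-per-class 60,60 --dim 6 --seed 0 --out train.csv
scakit fit train.csv --method sca --out model.json
scakit transform train.csv --model model.json --label-column label --out transformed.csv
scakit evaluate-beta-sweep train.csv test.csv --method sca --out rates.csv
```

## Layout

- `scakit.graph_embedding` — Laplacians, partial labels, scatter matrices
- `scakit.linear_transformers` — PCA, LDA, SCA (primal)
- `scakit.kernel_transformers` — dual forms: KPCA, KDA, KSCA, KLPP, KSDA
- `scakit.baselines` — similarity graph, LPP, SDA
- `scakit.classifiers` — 1-NN, nearest-mean, recognition rate
- `scakit.evaluation` — label removal, β-sweep, stratified CV, grid search
- `scakit.synthetic_data` — Gaussian-mixture and ill-posed generators
- `scakit.cli_io` — table/model I/O and the `scakit` command

See `docs/methods.md` for the model details, numerical policies and
limitations.
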