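# Methods

## Model and assumptions

The regression model is a random vector functional link (RVFL) network: a
fixed random hidden layer (weights and biases i.i.d. uniform on [−1, 1])
plus direct input→output links, with only the output weights β trained.
Random-feature models of this kind assume that a moderate number of random
nonlinear features (default P = 100 Gaussian bumps, `g(u) = exp(−u²)`),
together with the linear pathway, span the regression function well; the
closed-form ridge solution makes training deterministic given the seed.

SLapRVFL adds two penalties to the squared-error objective:

* a **manifold (Laplacian) term** `(λ₁/2)·Tr((Hβ)ᵀL(Hβ))` with L the
  symmetric normalized Laplacian of the fully connected RBF similarity
  graph over the *training* samples. The underlying assumption is that
  patients who are close in feature space should receive similar
  predictions. The graph is built on the training fold only; prediction
  does not need L, so no out-of-sample graph extension is attempted.
* a **row-sparsity term** `(λ₂/2)·‖β‖₂,₁` (sum of row norms of β), which
  prunes whole inputs or hidden neurons, assuming a subset of the
  (d + P) design columns suffices.

### The printed objective vs the update rule

The formulation is sometimes written with a squared L2,1 penalty, but the
reweighting matrix `G_ii = 1/(2‖β_i‖₂)` and the closed-form update
`β = (HᵀH + λ₁HᵀLH + λ₂G)⁻¹HᵀY` are exactly the IRLS/majorize–minimize
scheme for the **unsquared** penalty `(λ₂/2)Σ‖β_i‖₂` (the fixed-G gradient
`λ₂Gβ` equals the subgradient `λ₂β_i/(2‖β_i‖)`). This package therefore
defines and traces the unsquared objective: it is the quantity the MM
argument proves non-increasing across iterations, and the solver's fixed
point satisfies its stationarity condition (verified in the tests against a
derivative-free minimizer and a residual check at ≤ 10⁻⁶ relative error).

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| `P` | hidden nodes | 100 | RMSE minimum of the sequential width scan |
| `lambda_ridge` | ridge λ of the initializer (and of the baseline RVFL) | 1.0 | the initializer's own λ is a free choice; 1.0 is a neutral default on z-scored features |
| `lambda1` | Laplacian coefficient λ₁ | 2⁻³ | selected by the sequential λ grid search |
| `lambda2` | L2,1 coefficient λ₂ | 2^(−2.5) | selected by the sequential λ grid search |
| `gamma` | RBF width γ of the similarity graph | 1/d on z-scored features | a standard kernel default; `"median"` switches to the median-pairwise-distance heuristic |
| `max_iter` | reweighting iterations | 10 | the RMSE-vs-iterations curve flattens (and then only oscillates) near 10 |
| `tol` | relative β-change for early exit | 10⁻⁶ | secondary stop; the primary stop is the fixed iteration count |
| `epsilon` | guard added to row norms in G | 10⁻⁸ | keeps G finite for exactly-zero rows; standard IRLS smoothing. The traced (unsmoothed) objective may rise by at most the ε slack, hence the 10⁻⁸ relative monotonicity tolerance |

All coefficients apply to targets in their natural units (kg here).

## Preprocessing: standardization and target centering

Features are z-scored with training-fold statistics (the binary gender
feature is encoded 0/1 before scaling). Both the random projections and the
RBF similarity are scale sensitive, so unstandardized blood-pressure ranges
would otherwise dominate both pathways.

The design matrix `H = [H1 H2]` deliberately contains no intercept column
(an opt-in `include_bias` flag adds one). With z-scored features the column
span of H is a (d+P)-dimensional subspace that generally cannot absorb a
target location far from zero — body weights average ~60 kg — and without
correction both models degrade to worse-than-mean prediction. The
estimators therefore center the target during fitting and add the training
mean back at prediction, the standard treatment for intercept-free
penalized linear models. This keeps H exactly in its two-block form while
making the penalties act on deviations rather than on the overall weight
level.

## Evaluation protocol

* **Pooled 10-fold CV**: indices are shuffled with a seed and split into
  near-equal folds; standardization, the similarity graph, and all training
  happen inside each training fold. Out-of-fold predictions are pooled and
  RMSE, Pearson R, R² (coefficient of determination, *not* R²=R·R),
  Bland–Altman and folded-ECDF statistics are computed once on the pooled
  vector, so agreement counts range over every sample exactly once.
* **Bland–Altman**: differences are `predicted − reference`; SD uses the
  n−1 denominator; limits of agreement are `mean ± 1.96·SD`; the CI of the
  mean uses the Student-t critical value with n−1 df (which, unlike a
  z-based CI, reproduces published agreement tables at n = 476);
  outside-interval counting uses strict inequality (ties have measure zero
  for continuous predictions).
* **Folded ECDF** ("mountain plot"): `min(F, 1−F)` of the empirical CDF of
  the differences, peaking at the median; the summary also reports the
  lowest/median/highest difference.
* **Sequential grid search**: width P over {10,…,140 step 10} with 50
  iterations and λ₁ = λ₂ = 1; then the iteration count 1…100 at the chosen
  P; then (λ₁, λ₂) jointly over 2⁻⁵…2⁰ in steps of 2^0.5 (11 × 11 = 121
  cells), each cell scored by pooled 10-fold RMSE, ties broken toward the
  smaller value. `SearchProtocol` exposes the grids so that small studies
  can shrink them.

## The synthetic cohort generator

`default_cohort_spec()` encodes a 476-patient hemodialysis cohort through
its published marginals: age 54.17 ± 14.22, gender 312/164 male/female,
BMI 22.96 ± 2.95, SBP 150.64 ± 29.36, DBP 88.32 ± 19.56, HR 73.41 ± 8.92,
years of dialysis 5.97 ± 3.22, with per-feature Pearson correlations to dry
weight of −0.2341, −0.4489, 0.9558, −0.1739, −0.1249, 0.1862, −0.1069.

The squared target correlations sum to ≈ 1.26 > 1, so *no* generator with
mutually independent features can realize them (with independent
regressors, Σr² = R² ≤ 1; BMI's 0.9558 alone would cap at ≈ 0.85).
Features therefore share a single standard-normal latent factor carrying
the target signal: feature j loads on the factor with weight chosen so its
population correlation with the target equals the requested value (binary
gender through a thresholded latent normal, with the point-biserial
attenuation factor divided out), and the target is
`y = 60 + sqrt(10² − noise_sd²)·f + N(0, noise_sd²)` kg with
`noise_sd = 2` kg by default. Dry-weight location/scale (60 ± 10 kg) and
the noise level are the package's own choices — no target summary
statistics were published — and are configurable.

What the generator does **not** emulate: feature–feature covariances other
than the induced `r_i·r_j` (none were published), non-Gaussian marginals,
nonlinear feature–target structure, and any redundancy or measurement-noise
pattern of the real cohort. Passing tests on these cohorts show the
machinery is correct and well calibrated, not that the model ranking on the
real cohort transfers: in particular, on this generator's exactly linear,
all-features-informative signal, the extra penalties of SLapRVFL have
nothing to prune and only add bias, and the ridge baseline is consistently
(if marginally, ~1–2% RMSE) the more accurate of the two — the opposite of
the published ranking on clinical data, whose reproduction requires the
private cohort. The paired-comparison acceptance test records this honestly
rather than recalibrating the generator to force agreement.

`generate_sparse_linear` provides the complementary fixture where sparsity
*is* the ground truth (a random size-k support of d standard-normal
features); there SLapRVFL's input-block row norms separate active from
inactive features by nearly two orders of magnitude.

## Numerical choices

* Linear systems are solved with a symmetric positive-definite
  factorization (fallback to a generic symmetric solver), never an explicit
  inverse; the ridge path verifies its residual at ≤ 10⁻⁶ relative and
  raises a descriptive error on numerically singular systems.
* `HᵀH + λ₁HᵀLH` is precomputed once per fit; only the diagonal λ₂G changes
  across reweighting iterations.
* Zero-variance feature columns pass through standardization unscaled.
* Fold sizes in k-fold CV differ by at most one; k = n gives leave-one-out.
* Model files are JSON; float64 round-trips are exact.

## Known limitations

* The dense n × n similarity graph is quadratic in training-fold size;
  fine at n ≤ ~500, not intended for large cohorts.
* λ₂ = 0 with a rank-deficient design has no unique minimizer; use λ₂ > 0
  or a positive initializer ridge.
* The manifold term penalizes prediction variation along *all* graph
  directions of a fully connected RBF graph; with very smooth targets this
  shrinks the prediction spread (see the generator discussion above).
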