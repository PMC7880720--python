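# slaprvfl

Sparse Laplacian-regularized random vector functional link (RVFL) networks
for clinical tabular regression, built around the problem of estimating the
**dry weight** of hemodialysis patients — the post-dialysis target body
weight that clinicians otherwise set by supervised trial and error or with
bioimpedance instruments — from seven routine demographic and anthropometric
features (age, gender, systolic and diastolic blood pressure, BMI, heart
rate, years of dialysis).

The package provides the model, the method-agreement evaluation toolkit used
to judge whether such a predictor can substitute for the clinical reference
(pooled 10-fold cross-validation, Bland–Altman analysis, folded empirical
CDF summaries), and a synthetic cohort generator that reproduces the
published marginal structure of a 476-patient hemodialysis cohort so that
everything is testable without access to clinical data.

## The model

An RVFL network is a one-hidden-layer network whose hidden weights
`a_j` and biases `b_j` are drawn once, uniformly on [−1, 1], and never
trained. The output layer regresses the target on the concatenated design
matrix

```
H = [H1  H2],   H1 = X,   H2[i,j] = g(a_j · x_i + b_j),   g(u) = exp(−u²)
```

so it sees both a linear (direct-link) and a nonlinear pathway. The baseline
RVFL trains only the output weights β by ridge regression,
`β = (HᵀH + λI)⁻¹ HᵀY`.

SLapRVFL augments that objective with two penalties:

```
min_β  ½‖Hβ − Y‖²_F  +  (λ₁/2)·Tr((Hβ)ᵀ L (Hβ))  +  (λ₂/2)·‖β‖₂,₁
```

* **Manifold smoothness** — `L = D^{−1/2}(D − S)D^{−1/2}` is the symmetric
  normalized Laplacian of the RBF similarity graph
  `S_ij = exp(−γ‖x_i − x_j‖²)` over the training samples; the quadratic form
  penalizes predictions that differ between similar patients.
* **Row sparsity** — the L2,1 norm `‖β‖₂,₁ = Σ_i ‖β_i‖₂` drives whole rows
  of β (inputs or hidden neurons) to zero.

The non-smooth L2,1 term is handled by iteratively reweighted least squares:
with the diagonal matrix `G_ii = 1/(2‖β_i‖₂)` frozen, the subproblem has the
closed form `β = (HᵀH + λ₁HᵀLH + λ₂G)⁻¹HᵀY`; alternating the G update with
this solve is a majorize–minimize scheme whose objective never increases.
The loop starts from the ridge RVFL solution and runs 10 reweighting
iterations by default, with λ₁ = 2⁻³, λ₂ = 2^(−2.5), P = 100 hidden nodes.

## Worked example

```
$ slaprvfl simulate --n 476 --seed 1 --out cohort.csv
wrote 476 samples to cohort.csv

$ slaprvfl evaluate --data cohort.csv
10-fold CV on 476 samples
  RMSE 3.2735  R 0.9295  R^2 0.8615
  Bland-Altman: mean -0.0279  SD 3.2768  CI [-0.3230, 0.2673]
  limits of agreement [-6.4504, 6.3947]  outside 22/476 (4.62%)
  differences: lowest -8.6574  median 0.0932  highest 10.1210

$ slaprvfl fit --data cohort.csv --out model.json
fitted on 476 samples in 8 iterations; final objective 2954.8161; saved to model.json
```

Reading the evaluation: every sample is predicted exactly once by a model
that never saw it (pooled out-of-fold predictions), giving an RMSE of
3.27 kg on a cohort whose dry weight has SD ≈ 10 kg (R² 0.86). The
Bland–Altman block summarizes agreement with the reference values: the mean
difference is −0.03 kg (no systematic bias; its 95% CI covers zero) and 95%
limits of agreement span roughly ±6.4 kg, with 4.62% of patients outside —
under the usual convention a method is clinically acceptable when at most
5% of points fall outside its limits. The last line gives the extremes and
median of the difference distribution, the numbers behind a folded-ECDF
("mountain") plot.

The same machinery is available as a library:

```python
from slaprvfl import (SLapRVFLRegressor, default_cohort_spec,
                      generate_cohort, kfold_cv)

X, y = generate_cohort(default_cohort_spec(seed=1))
cv = kfold_cv(X, y, SLapRVFLRegressor, k=10, seed=0)
print(cv.rmse, cv.bland_altman().loa_upper)
```

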