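# Methods

## Model

`washord` fits a cumulative-logit ordinal regression with two Gaussian
random-effect layers to household survey data georeferenced at the cluster
(primary sampling unit) level. The latent variable for household *i* is

z_i = x_i′β + u(s_i) + b_{c(i)},  P(y_i ≤ k) = logit⁻¹(θ_k − z_i),

with strictly increasing thresholds θ. Categories are coded 0..K−1 with 0
the least-improved reference level and K at most 5. The model has no fixed
intercept: an intercept is not identified jointly with the thresholds, so
location is absorbed into θ (the identifiability test in the suite checks
that a pure location shift of the generative scale lands in θ̂, not β̂).
Thresholds are parameterised unconstrained as θ_1 and log increments,
θ_k = θ_{k−1} + exp(λ_{k−1}), so the outer optimiser never sees the
monotonicity constraint.

All households in a cluster share the cluster's coordinates, so the spatial
field is evaluated once per cluster and shared; this mirrors how survey
coordinates are released (cluster-level, displaced) and is assumed rather
than estimated.

### Spatial field

u(s) is a stationary Matérn field with smoothness ν = 1 (α = 2 in d = 2 —
the standard SPDE default, which yields a sparse three-term precision),
represented on a triangulated mesh by the finite-element SPDE approach. The
mesh is the Delaunay triangulation of the cluster coordinates augmented
with a ring of boundary nodes extending the bounding box outward by
`buffer_fraction` of the point-cloud diameter (boundary-variance
mitigation) and, optionally, quasi-uniform filler nodes at spacing
`max_edge`. The mass matrix is lumped (diagonal), which keeps G C⁻¹ G — and
hence the precision

Q = τ² (κ⁴ C + 2 κ² G + G C⁻¹ G),  κ = √8 / range,  τ = 1/(√(4π) κ σ_u)

— sparse. The practical range is defined as √8/κ, the distance at which the
Matérn ν=1 correlation falls to (√8)K₁(√8) ≈ 0.139. The noise scaling τ is
chosen so the stationary marginal variance equals σ_u²; σ_u and the range
are estimated on the log scale. Coordinates are treated as planar Euclidean
(degrees used directly); at sub-continental desk scale the metric
distortion is a documented approximation, and no projection handling is
attempted.

Observation/prediction locations are linked to the mesh by barycentric
interpolation rows (≤3 nonzeros summing to 1). Locations outside the mesh
receive a zero row — no silent extrapolation — and are flagged in the
prediction mask.

### Estimation

The joint negative log-likelihood is the sum of the per-household ordinal
terms −log p_y(z), the N(0, σ_b² I) penalty for b, and the N(0, Q⁻¹)
penalty for the mesh weights w, all with normalising constants. The ordinal
term uses the identity σ(a) − σ(b) = σ(a)σ(−b)(1 − e^{b−a}) in log space,
which is stable for |θ − z| well beyond the ±35 the data can produce.

The cumulative-logit NLL is convex in z, so the inner problem (minimising
the joint NLL over v = (b, w) at fixed outer parameters) has a unique mode.
It is solved by Newton iterations with the exact sparse Hessian
H = JᵀDJ + blockdiag(σ_b⁻² I, Q), step halving to guarantee monotone
descent, and two stopping rules: gradient max-norm below `inner_tol`
(default 1e-8) or Newton decrement below 1e-13·(1+|f|) — the decrement rule
matters when H is ill-conditioned and solve round-off puts a floor under
the achievable gradient norm. The per-observation curvature D is floored at
1e-10 to keep H positive definite in flat likelihood tails. The Laplace
marginal criterion is JNLL(mode) + ½ log det H − (n_re/2) log 2π.

The outer parameters (β, θ_1, λ, log σ_b, log range, log σ_u — at most
p+K+2 of them) are optimised by L-BFGS-B with central-difference gradients,
followed by up to three Newton polish steps on the central-difference
Hessian. The polish exists because quasi-Newton line searches stall on
function-value stagnation near the optimum (the marginal NLL is computed
through an iterative inner solve and has a noise floor around 1e-7), while
one or two exact Newton steps reliably push the measured gradient norm to
the 1e-3–1e-5 range. The final finite-difference Hessian, inverted, is the
reported parameter covariance; if it is not positive definite the
pseudo-inverse is used with a warning. The fit is deterministic: starting
values are fixed functions of the data (β = 0, thresholds from the logits
of empirical cumulative frequencies, σ_b = 0.5, range = ¼ of the domain
diameter, σ_u = 0.5) and nothing random enters the optimisation.

Sparse log-determinants use SuperLU (`scipy.sparse.linalg.splu`, summing
log |diag(U)|, valid for the symmetric positive-definite matrices involved);
sampling from N(mode, H⁻¹) or N(0, Q⁻¹) uses dense Cholesky factors, which
is comfortable at the mesh sizes this package targets (10²–10⁴ nodes).

### Prediction and uncertainty

Grid prediction evaluates z* = x*′β̂ + A*ŵ with the cluster effect at its
mean 0 — clusters are design artifacts, not map features. The time
covariate is supplied as a prediction date and standardized with the
*training* statistics. Delta-method variances use
Var(z*) = x*′Cov(β̂)x* + a*′Cov(w | data)a*, where conditional-covariance
columns come from sparse solves against H. Two approximations are
deliberate and documented: the β–w cross-covariance is omitted, and
threshold uncertainty is excluded (plug-in thresholds), matching a
first-order treatment of the linear predictor only. Both field and
fixed-effect terms are separately toggleable. The parametric Monte-Carlo
check in the acceptance suite (β and w drawn from their estimated
Gaussians) brackets the combined effect of these omissions within a factor
1.5 — except where ∂p_k/∂z ≈ 0 (an interior category at its probability
peak), where the first-order SE is exactly 0 by construction and only
second-order terms remain; comparisons there are excluded by a sensitivity
floor |∂p_k/∂z| ≥ 0.05.

Rasters are float32 GeoTIFFs, EPSG:4326, NaN nodata, north-up, cell-edge
origin, written through `tifffile` with standard georeferencing tags
(ModelPixelScale, ModelTiepoint, GeoKeyDirectory, GDAL_NODATA); the round
trip is bit-exact.

### Diagnostics

* **Dunn–Smyth residuals**: r_i = Φ⁻¹(u_i), u_i uniform on the cumulative
  probability interval of the observed category; exactly standard normal
  when the probabilities are correct. Seeded and clipped at 1e-12.
* **Calibration**: per-class equal-width bins (10 by default — the binning
  is a free choice); empty bins are kept with zero counts, never dropped.
* **Posterior predictive checks**: replicate outcome vectors drawn with
  random effects sampled from the Laplace Gaussian N(mode, H⁻¹) (a
  mode-fixed variant is a flag); the headline statistic is the max absolute
  category-frequency difference.
* **Classification metrics**: argmax prediction (ties to the lowest
  category), one-vs-rest AUC via the rank statistic with midrank ties
  (scikit-learn), precision/recall/F1 from the binarised confusion matrix;
  "accuracy" is one-vs-rest accuracy per class. Classes without both
  positives and negatives are flagged undefined rather than scored.
* **Shapley attributions**: for a linear predictor under feature
  independence the Shapley value has the exact closed form
  φ_ij = β_j(x_ij − x̄_j); attributions are computed on η only (spatial and
  cluster effects are not features), and ranked by mean |φ|.

## Synthetic data generator

The generator emulates DHS/MICS-style cluster sampling: clusters uniform
over a lon/lat bounding box, 25–30 households per cluster (uniform counts),
cluster-level covariates, and outcomes drawn from the model above — the
generator *is* the model, which is what makes downstream self-consistency
checks meaningful. Defaults: K = 4, β = (0.8, −0.5, 0.6, 0.3) on two
standardized continuous surfaces + an urbanicity factor + log-time,
thresholds (−1.2, 0, 1.2), σ_b = 0.5, range = 3° on a 10°×10° domain,
σ_u = 0.8 — moderate effects with all three variance components of
comparable size, so no single component dominates recovery tests.

Continuous covariates are smooth low-order trend surfaces (seeded quadratic
plus one harmonic, normalised to unit scale) plus iid cluster-level noise
(SD 0.3); smoothness keeps covariates distinguishable from the spatial
field while the noise keeps the design well conditioned. Categorical
covariates threshold a seeded latent surface at quantile cutpoints matching
the requested level probabilities, so survey and prediction grid see one
consistent surface. The time covariate is the natural log of days since
2005-01-01, with per-cluster survey dates uniform over 2006–2023 and the
prediction default 2024-01-01. Continuous and time covariates are
standardized over the training households; grids always reuse the training
means/SDs. All randomness flows through one seeded generator in a fixed
stream order (coordinates, counts, covariates, b, u, y), making datasets
byte-reproducible.

`sample_grf` draws Matérn fields from the exact dense covariance
σ_u²(κh)K₁(κh) (Cholesky) up to a configurable size cap, with 1e-8 diagonal
jitter and a warning on duplicate coordinates; above the cap it switches to
the SPDE representation on an auto-built mesh. The dense path is the oracle
the SPDE path is tested against.

What the generator does **not** emulate: DHS coordinate displacement,
survey weights, urban/rural oversampling beyond a categorical covariate,
covariate measurement error, and real-world covariate collinearity
structures. Passing tests therefore demonstrate internal consistency of the
estimation machinery under the model's own assumptions, not robustness to
the ways real surveys violate them.

## Problem sizes and numerical choices

The replicate studies use 150 clusters × 25 households (K = 4, p = 3) for
parameter recovery, a 200-cluster fit for calibration/PPC/delta-method
checks, and a ~3000-node mesh for the SPDE-vs-Matérn comparison — sizes
chosen so each study completes in minutes while keeping Monte-Carlo noise
well inside the tolerance bands. Wald coverage is assessed at the 95%
level over 20 replicates; hyperparameter recovery is summarised by median
absolute error on the log scale, the natural scale for variance and range
parameters.

Key tolerances: inner Newton 1e-8 (gradient) with the decrement fallback;
outer gradient target 1e-5, with the measured finite-difference gradient
accurate to roughly 1e-3 at the objective's noise floor; finite-difference
Hessian step 1e-4 relative. Degenerate inputs are errors, not warnings:
non-positive range, σ_u = 0 in the precision (callers drop the field
instead), unobserved categories (merge before fitting), meshes from
collinear points.

## Known limitations

* Planar-coordinate approximation; no spherical SPDE, barriers, or
  anisotropy.
* One spatial field per fit; no temporal random field (time is a fixed
  effect only) and no survey weights.
* Outer inference is Wald/plug-in; no profile likelihood or full Bayes.
* The first-order delta SE vanishes at interior-category probability peaks;
  the Monte-Carlo path in `prediction`'s acceptance check is the remedy
  when those cells matter.
* Dense Cholesky in field sampling and PPC bounds practical mesh sizes to
  ~10⁴ nodes; the estimation path itself is fully sparse.
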