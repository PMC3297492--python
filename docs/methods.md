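# Methods

## Model

A biological form is an ordered configuration `C = {l_j | j = 1..K}` of
homologous landmarks (K×3 or K×2, millimetres).  Superimposition removes the
confounders of position, orientation and optionally size through a
similarity transform `T(l, θ) = s·R·l + t`; residuals `d_j = T(l'_j, θ) − l_j`
then carry the form difference.  Under the classical homoscedastic Gaussian
perturbation model the maximum-likelihood superimposition is the
least-sum-of-squares (LSS) Procrustes fit.  That estimator has an unbounded
influence function: one grossly displaced region biases the pose estimate
without limit (the Pinocchio effect).

`dysmorph` extends the likelihood with an explicit outlier process.  Each
residual is generated either by the AWGN inlier process, with density on
the residual magnitude

    Pr_i(d) = 1/(√(2π)·σ) · exp(−‖d‖² / 2σ²),

or by a uniform outlier process of constant level δ, selected by a latent
Bernoulli indicator `z_j`.  Folding the Bernoulli prior and δ into one
constant λ, the EM treatment gives the posterior inlier belief

    b_j = Pr_i(d_j) / (Pr_i(d_j) + λ) = expit((κ² − ‖d_j‖²/σ²) / 2),

with λ re-parameterized as `λ = exp(−κ²/2)/(√(2π)σ)`.  Because λ shares the
Gaussian prefactor, the belief depends only on the Mahalanobis ratio
`‖d_j‖/σ` and on κ, and crosses ½ exactly at `‖d_j‖ = κσ` — κ is an explicit
Mahalanobis outlier threshold, i.e. a per-landmark significance level.  The
equivalent M-estimator of the resulting Q-function is redescending (a smooth
approximation of the truncated quadratic): fully inlying landmarks are fitted
exactly as in the classical Procrustes estimator, fully outlying ones
contribute nothing to pose or σ.

The EM loop alternates:

* **E-step** — evaluate beliefs from the current residuals and (σ, κ); λ is
  refreshed from the current σ̂ each E-step so the outlier threshold adapts
  as the noise estimate sharpens.
* **M-step** — belief-weighted LSS fit (closed form: weighted centroids +
  weighted cross-covariance SVD with a proper-rotation guard), then
  σ̂² = Σ b_j‖d_j‖² / Σ b_j.

The dysmorphogram is the soft map `1 − b_j` painted on the landmarks,
together with the residual magnitudes; thresholding at ½ is offered only as
a convenience view.

### Norms and transformation models

*Single-configuration norm* (change and asymmetry assessments): the rigid /
similarity model above; no transformation is favored, so the parameter prior
contributes nothing.

*Population norm* (discordancy): a point distribution model.  A cohort is
aligned by generalized Procrustes analysis (GPA), PCA of the aligned
coordinates keeps the top modes reaching a cumulative-variance fraction
(default 0.98), and the transformation model becomes
`T(C̄ + Σ_k U_k c_k, θ)`.  The mode loadings carry a Gibbs prior whose
negative log is the Mahalanobis penalty `½ Σ_k c_k²/α_k²`; the M-step then
alternates the weighted rigid update with the regularized linear solve for
`c` (3 inner passes).  The fitted instance is the norm-equivalent of the
assessed configuration, and discordancy is whatever still disagrees with it
beyond the estimated noise level.

### Asymmetry protocol

The configuration itself is the norm.  Its mirror image — reflection across
an arbitrary initial plane through the centroid, followed by swapping
left/right labels so homology is restored — is superimposed robustly onto
the original.  Asymmetric regions disagree with their mirror homologues and
surface as outliers.  Composing the initial reflection with the fitted rigid
map yields one improper orthogonal map whose −1-eigenvector is the subject's
midsagittal plane normal (the fixed points, from the least-squares solution
of `(I − A)x = g`, locate the plane).  The initial plane need not be
anatomically meaningful; the robust fit corrects it, which is precisely what
a least-squares fit cannot do in the presence of strong asymmetry.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `kappa` | 2.0 | Mahalanobis threshold at which the outlier belief overtakes the inlier belief; the per-landmark significance level.  κ = 6 effectively reproduces the unweighted LSS fit. |
| `allow_scale` | off | estimate a scale factor.  Off for change/asymmetry (same subject, absolute mm meaningful); optional for discordancy. |
| `tol` | 1e-9 | relative objective change declaring EM convergence |
| `max_iter` | 200 | EM iteration cap (`converged=False` beyond it) |
| `dim_factor` | 1 | divisor in the σ̂ update.  1 keeps σ on the residual-magnitude scale (see below); `dim` would put it on the per-coordinate scale. |
| `breakdown` | 0.25 | minimum mean belief; below it the fit aborts with a breakdown error rather than returning a meaningless pose |
| `variance_fraction` | 0.98 | PDM cumulative-variance retention |
| GPA `tol` / `max_iter` | 1e-8 mm / 100 | consensus RMS change stop rule |

### The σ scale convention

The inlier density is defined on the residual *magnitude* with the 1-D
prefactor `1/(√(2π)σ)`, and the M-step update `σ̂² = Σ b‖d‖²/Σ b` is the
exact minimizer of the Q-function under that convention.  Under isotropic
per-coordinate noise σ_c, the estimand is then `√dim·σ_c`;
`SuperimpositionResult.sigma_per_coord` converts back.  This convention is
load-bearing, not cosmetic: re-normalizing σ̂ to the per-coordinate scale
while keeping the belief boundary at `‖d‖ = κσ` shrinks the threshold to
κσ_c, which for 3-D data flags ~26 % of pure-noise landmarks at κ = 2 and
makes the EM noise estimate collapse (the flagged tail is removed from the
σ̂ moment, shrinking σ̂ further — a runaway that ends with ~60 % of clean
landmarks flagged).  On the magnitude scale the belief boundary sits at
`κ·√3·σ_c` for 3-D data; the implied per-landmark false-positive rate at
κ = 2 is P(χ²₃ > 12) ≈ 0.7 % (κ maps to a two-sided 1-D p ≈ 0.046 only if
the magnitude is treated as a single Gaussian deviate; the package reports,
and asserts nothing about, this mapping).

### Convergence bookkeeping

`objective_trace` records the negative Q at each iteration's end.  Because λ
is refreshed from σ̂ every E-step, no scalar Lyapunov function exists: the
trace may rise transiently (a few percent) right after the first outliers
are flagged and σ̂ contracts, then settles monotonically.  The stop rule is
relative change of this objective; σ̂ is floored at 1e-6 mm so that
noiseless data (exact alignment) cannot divide by zero.  Beliefs are kept
soft throughout — no hard assignment ever feeds back into the fit.

## Synthetic data

`dysmorph.synthetic` generates every input the tests and experiments use;
each function is a pure function of its seed (PCG64).

* `make_template(n, seed)` — a bilaterally symmetric half-ellipsoid "face"
  (~130 × 110 × 70 mm) with named regions (forehead, eyes, cheeks, jaw,
  nose, nose_tip, mouth, chin, midface), exact left/right label pairing and
  a midline.  The proportions are cartoonish by design: the protruding
  nose-tip region carries 12 % of the landmarks, so the Pinocchio
  experiment is well posed both for robust flagging at κ = 2 and for the
  unweighted limit at κ = 6 (with a much smaller nose the displaced region
  remains an outlier even at κ = 6 and the LSS limit is unreachable on
  noiseless data).
* `inject_deformation` — displaces exactly one named region along a vector
  or outward; the ground-truth outlier mask for every sensitivity /
  specificity measurement.
* `add_awgn` — isotropic Gaussian landmark noise (scan + mapping error).
* `make_modes` / `sample_population` — smooth orthonormal deformation
  fields, projected off the similarity-group tangent space at the template
  so they carry pure shape variation (components a Procrustes alignment
  would silently absorb are removed *before* sampling), and cohorts
  `template + Σ c_k·mode_k + noise` with optional random pose.

What the generator does **not** emulate: real facial anatomy, correlated or
heteroscedastic landmark noise, surface topology, missing landmarks, and
outlier displacements that are themselves smooth deformations of extended
regions.  Passing tests therefore demonstrate the estimator's statistical
behavior under its stated model, not clinical validity on scanned faces.

## Experiment sizes and numerical choices

* Pinocchio experiments use 1,000-landmark templates (a desk-scale stand-in
  for spatially dense quasi-landmark sets; a 10,000-landmark profile is used
  for the runtime-scaling check, which asserts growth ratios only, never
  wall-clock).
* Parameter-recovery: 50 replicates, 500 landmarks, σ = 0.5 mm, 10 % of
  landmarks displaced 10σ in random directions, random rigid truth.
  Rotation error is the angle of `R̂·R_true`; translation error is measured
  at the observed centroid (the gauge-free decomposition — the raw
  translation vector conflates rotation error with the ~60 mm lever arm of
  the origin).
* PDM recovery: 200 faces, 300 landmarks, 3 modes (SDs 8/5/3 mm in
  field-norm units), cohort digitization noise 0.001 mm.  Near-noiseless
  training data is required for sub-milliradian subspace recovery: PCA
  subspace error grows like (σ_noise/σ_mode)·√(p/n).  Mode subspaces are
  compared modulo the similarity-group tangent space, since aligned shape
  variation is defined only in that quotient; held-out assessment faces get
  realistic 0.5 mm noise.
* GPA initializes the consensus with the mean of the centered inputs, making
  the result invariant to input order (initializing from the first
  configuration would leave the final frame order-dependent).
* SVD fits guard against reflections by flipping the last singular vector
  when `det < 0`; degenerate (collinear/coincident) effective landmark sets
  raise rather than return an arbitrary rotation.
* LMedS uses 500 minimal subsets of size `dim` and refines on inliers within
  2.5 robust SDs (with the usual small-sample correction).  The repeated-
  median resistant fit is a reference baseline only: 2-D exact, 3-D via
  iterated axis-wise repeated medians of pairwise in-plane angles; its cost
  is quadratic in K and its convergence theory murky.

## Limitations

* A single scalar σ: no per-landmark or correlated (full model-metric) noise
  structure, and no tangent-space projection — appropriate for small
  residual scales relative to form size.
* κ is a *per-landmark* significance level; no multiple-testing correction
  across landmarks is applied.  At κ = 2 a fraction ~0.7 % of clean
  landmarks will be flagged by construction.
* Abnormality mass must stay below the estimator's breakdown point; the
  package guards at mean belief 0.25 and errors out rather than degrading
  silently.
* The outlier process is a fixed uniform density; spatial coherence of
  outliers (neighbouring landmarks failing together) is not modelled.
* Landmark correspondence is assumed given (label order).  Establishing
  correspondence — surface registration, semi-landmark sliding — is out of
  scope.
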