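# Methods

## The model

Interocular suppression — a salient competitor in one eye degrading
discrimination of a target in the other — is modeled as the joint action of
two mechanisms acting on populations of monocular neurons:

1. **Divisive normalization across eyes.** Each monocular population's
   responses are divided by a suppressive drive that pools its own eye's
   stimulus drive plus the other eye's drive weighted by an interocular
   normalization weight `w_I`.  This pathway produces contrast-gain changes
   (rightward shifts of the psychometric function on log contrast) for every
   competitor, whatever its size.
2. **Attentional gain modulation.** The abrupt competitor onset draws
   stimulus-driven attention that raises the gain of neurons matched to the
   competitor and lowers the gain of neurons matched to the target, while
   goal-driven attention (set by the discrimination task) does the opposite
   around the target orientation.  Because attention multiplies the drive in
   both the numerator and the normalization pool, a *spatially narrow*
   attentional footprint changes the asymptote (response gain) whereas a
   *wide* footprint rescales contrast (contrast gain) — the classic
   attention-normalization interaction, here driven by competitor size.

Each eye's population is a 2-D array of neurons over RF center
`x ∈ [-20°, 20°]` and preferred orientation `θ ∈ [0°, 180°)`:

    R_L(x,θ) = A_x A_v E_L^n / (S_L + w_I S_R + σ^n),   and mirrored for R_R

with

* excitatory drive `E` — stimulus contrast × the RF Gaussian (SD 1.5°)
  integrated over the stimulus aperture × a circular-Gaussian orientation
  tuning curve (48° FWHM);
* suppressive drive `S = K * (A_x A_v E^n)` — a convolution (linear in x,
  circular in θ) with a kernel `K(Δx, Δθ) = exp(-Δx²/2σ(Δθ)²)`,
  `σ(Δθ) = 6° · exp(-|Δθ|/20°)`: broadly tuned for orientation inside the RF,
  narrowly tuned in the surround;
* attention fields with baseline 1, built from a feature profile
  `a_θ = exp(k(cos 2Δθ - 1)) - 0.5` (k = 3, 40° FWHM, range ≈ ±0.5) and a
  spatial profile `a_x = σ_ax^(-p) (2π)^(-1/2) exp(-x²/2σ_ax²)`, where `p`
  trades magnitude against extent (p = 1: fixed volume).

Two stimulus-driven variants are compared.  **FS (feature-specific)**:
`A_x = w_x a_θ a_x + 1`, centered on the competitor orientation with
`σ_ax` equal to the *fused* competitor width, identical in both eyes — hence
the split competitor (center in one eye, annular surround in the other)
produces exactly the field of the large competitor.  **ES (eye-specific)**:
no orientation selectivity; each competitor component of width d raises the
gain in its own eye by `w_x a_x(x; d, p)` and lowers the other eye's gain by
the same amount, deviations adding across components.  A **compound**
variant multiplies an FS field (magnitude `w_x`) and an ES field (magnitude
`w_x_eye`).  Goal-driven attention `A_v = w_v a_θ a_x + 1` is centered on the
target orientation with fixed `σ_ax = 60°`, `p = 0`, identical everywhere and
in every condition.

Behavioral sensitivity is read out from the single neuron best matched to the
target (eye, orientation, RF center) under additive IID noise:
`d' = R_target / σ_n`, and `P(correct) = Φ(d'/2)` for the unbiased two-choice
identification task.

Free parameters (7): `n, σ, w_I, w_x, w_v, p, σ_n`.  Optional: directional
interocular weights `w_LR / w_RL` (suppression from the left-eye stimulus
onto the right-eye population and vice versa) replace `w_I` for eye-swap
designs; `w_x_eye` joins for the compound variant.

## Numerical conventions

* **Grid.** Default 0.25° RF-center step and 1° orientation step (161 × 180
  neurons per eye).  Fitting-heavy analyses use 0.5° / 3°; predicted d'
  differs by < 0.1 % between the two (a convergence test asserts < 1 % when
  the step is halved).
* **Kernel sampling and normalization.** The suppressive field's spatial
  width collapses to 0.07° at 90° orientation offset — far below any
  reasonable grid step — so kernel rows are sampled as the *average* of the
  Gaussian over each Δx cell (midpoint sampling converges only first-order in
  the step).  The kernel is normalized to unit volume, making `S` a weighted
  average of the modulated drive.  Any kernel scale is formally absorbed by
  `σ`, so this is a units convention; it is chosen so that the published
  best-fit `σ` values (≈ 0.0016–0.002, in units of excitatory drive) produce
  realistic psychometric functions and can serve directly as generator
  defaults.
* **Point evaluation.** d' depends on one neuron, so the suppressive drive is
  evaluated as a weighted sum against a precomputed kernel slice rather than
  a full convolution; for an eye carrying a single stimulus component the
  contrast dependence factors out analytically.  The point path is tested to
  agree with the full-field path to 1e-12, and the FFT convolution against a
  brute-force double loop to 1e-10 relative.
* **Optimization.** Bounded L-BFGS-B from multiple seeded starts (bounds:
  n ∈ [0.5, 6], σ ∈ [1e-5, 0.1] log-scaled, w_I ∈ [0, 5], w_x, w_v ∈ [0, 10],
  p ∈ [0, 1], σ_n ∈ [0.1, 20] log-scaled).  The non-negativity constraint on
  the attention gains is an exact hinge penalty added to the least-squares
  objective; mildly infeasible points are evaluated as-is so the objective
  stays smooth across the boundary, where the goal-driven magnitude
  characteristically sits (w_v ≈ 5.04 makes the orthogonal-orientation gain
  exactly zero).
* **Descriptive fits.** Naka-Rushton least squares with the exponent shared
  across conditions: a two-stage grid over (n_d, log c50) with the asymptote
  profiled out in closed form, parabolic refinement, and (outside bootstrap
  loops) a Levenberg-Marquardt polish.  Bounds: c50 within [min contrast/10,
  max contrast × 10], d'_m ∈ [0, 10]; bound hits are flagged.  Noise-free
  recovery is better than 1 % relative.
* **d' estimation.** `d̂' = 2 Φ⁻¹(p̂)` with `p̂` clipped to
  [1/(2n), 1 − 1/(2n)].  The generator uses the exact inverse, making
  generation → estimation self-consistent.  Near ceiling this estimator is
  heavy-tailed (a 50/50-correct cell maps to d̂' = 4.65): see Limitations.
* **Hessian.** Central differences at the optimum (relative step 1e-4, with
  automatic shrinking), rank from singular values at tolerance
  `dim · eps · s_max`, and the smallest-eigenvalue eigenvector reported with
  its projection on each free parameter.  Eigenvector projections are
  coordinate-dependent: with only 8°-wide competitors the flat direction is
  the exact `w_x · 8^{-p}` trade-off, whose unit vector in (w_x, p)
  coordinates has slope `w_x ln 8`.

## Synthetic study design

The generator emulates the study: 4 observers × 5 competitor configurations
(none / 1.5° / 2.5° / 8° / split 8°-with-1.5°-center, competitor fixed at
23 % RMS contrast, target 1.5° at 45°) × 9 target contrasts × ≥ 50
independent Bernoulli trials per cell with `P(correct) = Φ(d'/2)`.  The nine
contrasts are log-spaced from 0.3 % to 35 % — the study's ladder is not
published; this range brackets the predicted psychometric functions
(no-competitor c50 ≈ 0.9 %, asymptote reached well inside the ladder).
Default observers use the published per-observer best fits, whose
heterogeneous `w_I` (0.01–3.81) reproduces the signature individual
differences: the low-`w_I` observer is hurt more by the split competitor
(its surround shares the target eye and is normalized with weight 1), the
high-`w_I` observer more by the large competitor.  An eye-swap session
generator emits the three-condition design (none / large / split) with the
target in the other eye; with directional weights the more-suppressive
condition flips between sessions.  A lapse rate (default 0) is available for
robustness checks.

What the generator does **not** emulate: sequential dependencies, lapses and
criterion drift, rivalry dynamics (target reappearance during the trial),
observer-specific contrast ladders, and any mismatch between the model family
and real visual cortex.  Passing pipeline tests on this synthetic data
therefore certify the *statistical machinery* (estimators, bootstrap,
cross-validation, identifiability analysis) and the model's internal
consistency — not the model's adequacy for new empirical data.

## Analysis pipeline

* **Descriptive bootstrap.** Trials are resampled with replacement within
  each (observer, condition, contrast) cell — implemented as a Binomial(n, p̂)
  draw, which is the exact distribution of a within-cell trial resample —
  each resample is refit per observer, per-condition parameters are averaged
  across observers, and two-sided p-values for Δc50 and Δd'_m between
  conditions are twice the smaller tail fraction (floored at 1/B; B = 2000 by
  default).
* **Model comparison.** (i) Trial-level split-half cross-validation: both
  variants are fit to the group-averaged training half (warm-started from
  their full-data fits) and scored by R² on the held-out half; the
  distribution of `R²_FS − R²_ES` over B partitions is the index, with a 95 %
  exceedance decision rule.  (ii) BIC with a binomial likelihood of per-cell
  correct counts pooled across observers under `P(correct) = Φ(d'_model/2)`
  (probabilities clipped to [1e-6, 1−1e-6]), `BIC = k ln N_cells − 2 lnL`.
  The likelihood construction is this package's convention.

## Problem sizes

Fitting-heavy analyses (cross-validation, parameter recovery, bootstrap
power studies) run on the 0.5°/3° grid with 20 replicate cohorts, B = 200
cross-validation resamples and B = 500 bootstrap resamples; single fits and
the worked-example evaluations use the reference 0.25°/1° grid and B = 2000
defaults.

## Known limitations

* Near-ceiling cells make `d̂'` heavy-tailed, which inflates the bootstrap
  variance of asymptote differences; with 4 × 50 trials per cell the
  medium-competitor response-gain reduction (Δd'_m ≈ −0.55) reaches
  significance in only ~3/4 of synthetic cohorts.
* When the FS model itself generates the data, the ES variant can mimic the
  group-averaged curves to R² ≈ 0.995, so split-half cross-validation at
  50 trials/cell separates the variants in only ~75–80 % of resamples; BIC
  still prefers the generating variant.  Real data are harder for the ES
  variant than FS-generated data are.
* The model is static (no rivalry dynamics), one-dimensional in space, and
  has no response rectification; σ is only defined up to the kernel-volume
  convention above.
* `w_I` is weakly identified without eye-of-origin manipulations (the
  five-condition design constrains it far better than the four-condition
  one); recovery of `w_I` is reported rather than asserted.
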