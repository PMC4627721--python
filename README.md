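# dichoptic

A computational model of **interocular suppression** — the loss of visibility
of a monocular target when a salient competitor is shown to the other eye —
and the psychophysics analysis pipeline built around it.  The package is
aimed at visual psychophysicists and computational neuroscientists who want
to simulate, fit, and compare normalization-model accounts of dichoptic
masking / onset flash suppression experiments.

## The model

Two populations of monocular neurons (left/right eye), indexed by receptive
field center *x* and preferred orientation *θ*, respond as

```
R_L(x,θ) = A_x A_v E_L^n / (S_L + w_I S_R + σ^n)        (mirrored for R_R)
```

* **E** — excitatory drive: contrast × RF-Gaussian overlap (SD 1.5°) ×
  orientation tuning (48° FWHM).
* **S = K ∗ (A_x A_v Eⁿ)** — suppressive drive: the attention-modulated drive
  pooled by a kernel that is broadly tuned for orientation within the RF and
  narrowly tuned in the surround; `w_I` weights the *other* eye's pool
  (interocular divisive normalization).
* **A_x** — stimulus-driven attention drawn by the competitor onset, with a
  feature profile `a_θ = exp(k(cos 2Δθ − 1)) − 0.5` (k = 3) and spatial
  profile `a_x = σ_ax^(−p) (2π)^(−1/2) exp(−x²/2σ_ax²)`, `σ_ax` = competitor
  size.  Two variants: **FS** (feature-specific, `A_x = w_x a_θ a_xᵀ + 1`,
  same in both eyes) and **ES** (eye-specific, gain up in the competitor's
  eye and down in the other, no orientation selectivity).
* **A_v** — goal-driven attention to the target orientation
  (`A_v = w_v a_θ a_xᵀ + 1`, σ_ax = 60°, identical in all conditions).
* Behavior: `d′ = R(target neuron)/σ_n`, `P(correct) = Φ(d′/2)`.

Normalization produces contrast-gain changes (shifts of the psychometric
function's semi-saturation contrast c50) for every competitor; narrow
attentional footprints produce response-gain changes (reduced asymptote
d′_m).  The **split competitor** — an 8° pattern whose 1.5° center goes to
one eye and whose annular surround goes to the other — dissociates the FS
and ES variants: FS predicts it behaves exactly like the large competitor,
ES predicts small-competitor-like behavior.

The descriptive layer fits Naka-Rushton psychometric functions
`d′(c) = d′_m cⁿ/(cⁿ + c50ⁿ)` with a shared exponent across conditions and
bootstraps Δc50 / Δd′_m between conditions; the fitting layer estimates the
seven model parameters (n, σ, w_I, w_x, w_v, p, σ_n) by bounded least
squares and compares variants by trial-level cross-validation and BIC.
See `docs/methods.md` for conventions and limitations.

## Worked example

```python
from dichoptic import (FS_GROUP_PARAMS, NeuronGrid, NormalizationModel,
                       StudyDesign, fit_descriptive, generate_trials)

grid = NeuronGrid(dx=0.5, dtheta=3.0)          # analysis grid
design = StudyDesign(observers={f"O{i}": FS_GROUP_PARAMS for i in range(1, 5)},
                     trials_per_cell=50)
trials = generate_trials(design, variant="fs", seed=7, grid=grid)  # 9000 trials

fit = fit_descriptive(trials)                   # Naka-Rushton per condition
print(fit.params[["condition", "d_m", "c50"]].round(4))

model = NormalizationModel(variant="fs", grid=grid, n_starts=6, seed=0).fit(trials)
print(model.r_squared_, model.params_)
print(model.gain_report())
```

prints (descriptive fit, shared exponent n_d = 2.01, R² = 0.962):

```
condition    d_m    c50
    large 2.7319 0.0215
   medium 2.3644 0.0209
     none 2.9372 0.0093
    small 1.6492 0.0198
    split 2.6605 0.0220
```

The no-competitor curve saturates at d′ ≈ 2.9 with c50 ≈ 0.9 % contrast; the
small competitor mainly halves the asymptote (response gain), while the
large and split competitors mainly shift c50 (contrast gain) by ~2.3× and
leave the asymptote nearly intact — the signature pattern of attention plus
interocular normalization.  The model refit recovers the generating
parameters (R² = 0.959; n = 1.97, w_x = 4.44, w_v = 5.01, p = 0.22,
σ_n = 2.85 against true 1.95 / 4.24 / 5.03 / 0.13 / 2.92) and its gain
report shows the per-condition stimulus-driven gains at the target neuron
(1.00, 0.19, 0.28, 0.44, 0.44) with the split and large conditions exactly
equal, and a goal-driven gain of 2.0.

The same pipeline is scriptable from the shell:

```bash
dichoptic generate --trials-per-cell 50 --seed 7 --out trials.csv
dichoptic fit-descriptive --trials trials.csv --out descriptive.yaml
dichoptic fit-model --trials trials.csv --variant fs --out fit.yaml
dichoptic compare --trials trials.csv --cv-b 200 --seed 1 --out compare.yaml
dichoptic report --results fit.yaml
```

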