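"""Normalization model of interocular suppression.

Two populations of monocular neurons (one per eye), each indexed by RF center
``x`` and preferred orientation ``theta``, respond to a dichoptic stimulus
according to

    R_L(x, theta) = A_x A_v E_L^n / (S_L + w_I S_R + sigma^n)

and symmetrically for the right eye.  The components are

excitatory drive ``E``
    linear in stimulus contrast, given by the overlap of the RF Gaussian with
    the stimulus aperture times the orientation tuning curve;
suppressive drive ``S``
    the attention-modulated drive ``A_x A_v E^n`` pooled over space and
    orientation by convolution with a suppression kernel whose spatial width
    shrinks for orientations away from the neuron's preference (suppression is
    broadly tuned inside the RF, narrowly tuned in the surround);
attentional gain factors
    ``A_x`` is stimulus-driven attention elicited by the abrupt competitor
    onset, either feature-specific (FS: selective for the competitor's
    orientation and extent, identical in both eyes) or eye-specific (ES: gain
    up in the competitor's eye, down in the other, uniform over orientation);
    ``A_v`` is goal-driven attention to the target orientation induced by the
    discrimination task.  Both have a baseline of 1.

Interocular suppression enters twice: through ``w_I`` (divisive normalization
across eyes) and through the stimulus-driven attentional gain, which lowers
the gain of target-tuned neurons.  Behavioral sensitivity d' is read out from
the single neuron best matched to the target (its eye, orientation and RF
center), divided by an additive noise magnitude ``sigma_n``.

The suppression kernel is normalized to unit volume, so the suppressive drive
is a weighted average of the modulated drive; with this convention the
semi-saturation constant ``sigma`` is on the same scale as the excitatory
drive and the reference parameter sets in :mod:`dichoptic.synthetic` produce
psychometric functions spanning the study's contrast ladder.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import ndtr

from .grid import NeuronGrid, wrap_orientation
from .stimulus import (
    Condition,
    StimulusComponent,
    expand_condition,
    fused_competitor_width,
)

__all__ = [
    "ModelParams",
    "excitatory_drive",
    "feature_profile",
    "spatial_profile",
    "stimulus_attention_fs",
    "stimulus_attention_es",
    "goal_attention",
    "suppression_kernel",
    "suppression_width",
    "suppressive_drive",
    "population_response",
    "predict_dprime",
    "predict_psychometric",
    "PsychometricPredictor",
]

# fixed model constants
SIGMA_SX = 6.0  # spatial width (deg) of the suppressive field at iso-orientation
TAU = 20.0  # orientation selectivity (deg) of surround suppression
FEATURE_K = 3.0  # concentration of the feature-attention profile (40 deg FWHM)
GOAL_SIGMA_AX = 60.0  # spatial extent (deg) of goal-driven attention
GOAL_P = 0.0  # goal-driven attention has no size-magnitude trade-off

VARIANTS = ("fs", "es", "compound")

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class ModelParams:
    """The free parameters of the normalization model.

    n
        exponent of the neural contrast-response function.
    sigma
        semi-saturation constant, in units of excitatory drive.
    w_I
        interocular normalization weight: how strongly the other eye's
        suppressive drive enters a population's normalization pool.
    w_x
        magnitude of stimulus-driven attentional modulation.
    w_v
        magnitude of goal-driven attentional modulation.
    p
        trade-off between the spatial extent and the magnitude of
        stimulus-driven attention (0 = none, 1 = fixed volume).
    sigma_n
        magnitude of the additive behavioral noise linking the target
        neuron's response to d'.
    w_LR, w_RL
        optional directional interocular weights: ``w_LR`` is the suppression
        contributed by the left-eye stimulus to the right-eye population and
        vice versa.  When unset, both directions use ``w_I``.
    w_x_eye
        magnitude of the eye-specific component in the compound variant
        (the FS component then uses ``w_x``).
    """

    n: float
    sigma: float
    w_I: float
    w_x: float
    w_v: float
    p: float
    sigma_n: float
    w_LR: float | None = None
    w_RL: float | None = None
    w_x_eye: float | None = None

    def validate(self) -> None:
        if self.n <= 0 or self.sigma <= 0 or self.sigma_n <= 0:
            raise ValueError("n, sigma and sigma_n must be positive")
        if self.w_I < 0 or self.w_x < 0 or self.w_v < 0:
            raise ValueError("attention and normalization weights must be >= 0")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")

    def interocular_weight(self, target_population_eye: str) -> float:
        """Divisive weight of the *other* eye's drive on this population."""
        if self.w_LR is None and self.w_RL is None:
            return self.w_I
        if target_population_eye == "right":
            return self.w_I if self.w_LR is None else self.w_LR
        return self.w_I if self.w_RL is None else self.w_RL

    def swap_directional(self) -> "ModelParams":
        return replace(self, w_LR=self.w_RL, w_RL=self.w_LR)


# ---------------------------------------------------------------------------
# excitatory drive
# ---------------------------------------------------------------------------

def spatial_overlap(x: np.ndarray, component: StimulusComponent, rf_sd: float) -> np.ndarray:
    """Integral of the RF Gaussian (SD ``rf_sd``) over the component aperture.

    Normalized so that an aperture covering the whole axis gives 1; the drive
    is therefore independent of the grid step.
    """
    x = np.asarray(x, dtype=float)
    lo = component.center_x - component.width / 2.0
    hi = component.center_x + component.width / 2.0
    ov = ndtr((hi - x) / rf_sd) - ndtr((lo - x) / rf_sd)
    if component.inner_width > 0:
        ilo = component.center_x - component.inner_width / 2.0
        ihi = component.center_x + component.inner_width / 2.0
        ov = ov - (ndtr((ihi - x) / rf_sd) - ndtr((ilo - x) / rf_sd))
    return ov


def orientation_tuning(theta: np.ndarray, orientation: float, tuning_sd: float) -> np.ndarray:
    """Circular Gaussian orientation tuning curve, peak 1."""
    d = wrap_orientation(np.asarray(theta, dtype=float) - orientation)
    return np.exp(-(d ** 2) / (2.0 * tuning_sd ** 2))


def excitatory_drive(
    components: list[StimulusComponent], grid: NeuronGrid
) -> dict[str, np.ndarray]:
    """Excitatory drive fields E(x, theta), one array per eye.

    Linear in contrast; an eye with no stimulus gets a zero field.
    """
    fields = {eye: np.zeros(grid.shape) for eye in ("left", "right")}
    for comp in components:
        gx = spatial_overlap(grid.x, comp, grid.rf_sd)
        ht = orientation_tuning(grid.theta, comp.orientation, grid.tuning_sd)
        fields[comp.eye] += comp.contrast * gx[:, None] * ht[None, :]
    return fields


# ---------------------------------------------------------------------------
# attentional gain profiles
# ---------------------------------------------------------------------------

def feature_profile(delta_theta: np.ndarray | float, k: float = FEATURE_K) -> np.ndarray | float:
    """Feature-based attention profile over orientation offset (deg).

    A von Mises bump shifted to range from about -0.5 (orthogonal) to +0.5
    (attended orientation):  exp(k (cos 2*dtheta - 1)) - 0.5.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    d = np.deg2rad(np.asarray(delta_theta, dtype=float))
    return np.exp(k * (np.cos(2.0 * d) - 1.0)) - 0.5


def spatial_profile(
    x: np.ndarray | float, x_a: float, sigma_ax: float, p: float
) -> np.ndarray | float:
    """Spatial attention profile over RF center (deg):

    a_x = sigma_ax^(-p) (2 pi)^(-1/2) exp(-(x - x_a)^2 / (2 sigma_ax^2)).

    With p = 1 the integral over x is independent of sigma_ax (fixed-volume
    attention); with p = 0 the peak is independent of the extent.
    """
    if sigma_ax <= 0:
        raise ValueError("sigma_ax must be positive")
    x = np.asarray(x, dtype=float)
    return sigma_ax ** (-p) / _SQRT2PI * np.exp(-((x - x_a) ** 2) / (2.0 * sigma_ax ** 2))


def _check_gain(field: np.ndarray | float, label: str) -> None:
    m = np.min(field)
    if m < -1e-9:
        raise ValueError(
            f"{label} attentional gain is negative (min {m:.4g}); "
            "w_x, w_v and p must keep all gains non-negative"
        )


def stimulus_attention_fs(
    components: list[StimulusComponent], grid: NeuronGrid, w_x: float, p: float
) -> dict[str, np.ndarray]:
    """Feature-specific stimulus-driven attention field, identical in both eyes.

    Gain is raised for neurons tuned to the competitor orientation within the
    fused competitor extent and lowered for orthogonally tuned neurons.  The
    split competitor fuses into the large one, so their FS fields are equal.
    Returns a unit field when no competitor is present.
    """
    if w_x < 0:
        raise ValueError("w_x must be >= 0")
    comps = [c for c in components if c.role == "competitor"]
    if not comps:
        ones = np.ones(grid.shape)
        return {"left": ones, "right": ones.copy()}
    sigma_ax = fused_competitor_width(components)
    theta_a = comps[0].orientation
    ax = spatial_profile(grid.x, 0.0, sigma_ax, p)
    at = feature_profile(grid.theta - theta_a)
    field = w_x * ax[:, None] * at[None, :] + 1.0
    _check_gain(field, "stimulus-driven (FS)")
    return {"left": field, "right": field.copy()}


def stimulus_attention_es(
    components: list[StimulusComponent], grid: NeuronGrid, w_x: float, p: float
) -> dict[str, np.ndarray]:
    """Eye-specific stimulus-driven attention fields, uniform over orientation.

    Each competitor component of width d raises the gain in its own eye by
    w_x * a_x(x; d, p) and lowers it by the same amount in the other eye.
    Deviations from the baseline of 1 add across components, so the split
    competitor favors the competitor eye centrally and the target eye in the
    surround.
    """
    if w_x < 0:
        raise ValueError("w_x must be >= 0")
    dev = {"left": np.zeros(grid.x.size), "right": np.zeros(grid.x.size)}
    for comp in components:
        if comp.role != "competitor":
            continue
        a = spatial_profile(grid.x, 0.0, comp.width, p)
        dev[comp.eye] += w_x * a
        dev["left" if comp.eye == "right" else "right"] -= w_x * a
    nt = grid.theta.size
    fields = {
        eye: np.repeat((1.0 + d)[:, None], nt, axis=1) for eye, d in dev.items()
    }
    for eye, f in fields.items():
        _check_gain(f, f"stimulus-driven (ES, {eye} eye)")
    return fields


def goal_attention(
    target_orientation: float, grid: NeuronGrid, w_v: float
) -> dict[str, np.ndarray]:
    """Goal-driven attention to the target orientation, identical in both eyes.

    Spatially almost uniform (Gaussian with sigma = 60 deg, no size-magnitude
    trade-off), feature-selective around the target orientation; the same in
    every condition because the task never changes.
    """
    if w_v < 0:
        raise ValueError("w_v must be >= 0")
    ax = spatial_profile(grid.x, 0.0, GOAL_SIGMA_AX, GOAL_P)
    at = feature_profile(grid.theta - target_orientation)
    field = w_v * ax[:, None] * at[None, :] + 1.0
    _check_gain(field, "goal-driven")
    return {"left": field, "right": field.copy()}


# ---------------------------------------------------------------------------
# suppression
# ---------------------------------------------------------------------------

def suppression_width(delta_theta: np.ndarray | float, sigma_sx: float = SIGMA_SX,
                      tau: float = TAU) -> np.ndarray | float:
    """Spatial width of the suppressive field at orientation offset dtheta."""
    d = np.abs(wrap_orientation(delta_theta))
    return sigma_sx * np.exp(-d / tau)


def suppression_kernel(
    grid: NeuronGrid,
    sigma_sx: float = SIGMA_SX,
    tau: float = TAU,
    normalize: bool = True,
) -> np.ndarray:
    """Suppression kernel K(dx, dtheta) on the offset grid.

    Rows are spatial offsets from -(nx-1)*dx to +(nx-1)*dx; columns are
    orientation offsets wrapped to [-90, 90) in ascending order.  K(0, .) = 1:
    within the RF, suppression pools all orientations; away from the RF center
    the pooling is narrowly tuned (sigma(dtheta) = sigma_sx exp(-|dtheta|/tau)).

    Because sigma(dtheta) shrinks below the grid step at large orientation
    offsets, each row is sampled as the average of the Gaussian over the dx
    cell rather than its midpoint value (otherwise the discrete sums that
    approximate the suppressive-drive integral converge only first-order in
    dx).  With ``normalize`` the kernel integrates to one over (dx, dtheta),
    making the suppressive drive a weighted average of the modulated
    excitatory drive, which puts ``sigma`` on the scale of the drive itself.
    """
    if sigma_sx <= 0 or tau <= 0:
        raise ValueError("sigma_sx and tau must be positive")
    nx = grid.x.size
    dx_off = grid.dx * (np.arange(2 * nx - 1) - (nx - 1))
    dt_off = kernel_theta_offsets(grid)
    sig = suppression_width(dt_off, sigma_sx, tau)[None, :]
    hi = (dx_off[:, None] + grid.dx / 2.0) / sig
    lo = (dx_off[:, None] - grid.dx / 2.0) / sig
    K = (ndtr(hi) - ndtr(lo)) * sig * np.sqrt(2.0 * np.pi) / grid.dx
    if normalize:
        K = K / (K.sum() * grid.cell_area)
    return K


def kernel_theta_offsets(grid: NeuronGrid) -> np.ndarray:
    """Ascending orientation offsets of the kernel columns, in [-90, 90)."""
    return np.sort(wrap_orientation(grid.theta))


def suppressive_drive(
    drive_pow: np.ndarray,
    a_x: np.ndarray,
    a_v: np.ndarray,
    kernel: np.ndarray,
    grid: NeuronGrid,
) -> np.ndarray:
    """Pool the attention-modulated drive with the suppression kernel.

    ``drive_pow`` is the exponentiated excitatory drive E^n of one eye.  The
    convolution is linear (zero-padded) along x and circular (period 180 deg)
    along orientation, and is scaled by the grid cell area so the result
    approximates the continuous integral.
    """
    modulated = np.asarray(a_x) * np.asarray(a_v) * np.asarray(drive_pow)
    if modulated.shape != grid.shape:
        raise ValueError(
            f"field shape {modulated.shape} does not match grid {grid.shape}"
        )
    nx, nt = grid.shape
    if kernel.shape != (2 * nx - 1, nt):
        raise ValueError(
            f"kernel shape {kernel.shape} does not match offset grid "
            f"{(2 * nx - 1, nt)}"
        )
    # reorder kernel columns so that the zero-orientation offset sits first
    # (circulant order for the FFT along the circular orientation axis)
    offs = kernel_theta_offsets(grid)
    j0 = int(np.argmin(np.abs(offs)))
    k_circ = np.roll(kernel, -j0, axis=1)
    # zero padding along x makes that axis a linear convolution; the
    # orientation axis is left unpadded, i.e. circular with period 180 deg
    L = modulated.shape[0] + kernel.shape[0] - 1
    FI = np.fft.fft2(modulated, s=(L, nt))
    FK = np.fft.fft2(k_circ, s=(L, nt))
    conv = np.fft.ifft2(FI * FK).real
    # rows nx-1 .. 2nx-2 hold the 'same'-aligned convolution along x
    S = conv[nx - 1: 2 * nx - 1, :] * grid.cell_area
    return S


def _brute_force_suppressive_drive(
    drive_pow: np.ndarray,
    a_x: np.ndarray,
    a_v: np.ndarray,
    kernel: np.ndarray,
    grid: NeuronGrid,
) -> np.ndarray:
    """Double-loop reference implementation (for validation on small grids)."""
    modulated = a_x * a_v * drive_pow
    nx, nt = grid.shape
    offs = kernel_theta_offsets(grid)
    j0 = int(np.argmin(np.abs(offs)))
    S = np.zeros((nx, nt))
    for i in range(nx):
        for j in range(nt):
            acc = 0.0
            for ii in range(nx):
                for jj in range(nt):
                    kx = i - ii + nx - 1
                    kt = (j0 + (j - jj)) % nt
                    acc += kernel[kx, kt] * modulated[ii, jj]
            S[i, j] = acc * grid.cell_area
    return S


# ---------------------------------------------------------------------------
# responses and the behavioral read-out
# ---------------------------------------------------------------------------

def attention_fields(
    components: list[StimulusComponent],
    grid: NeuronGrid,
    params: ModelParams,
    variant: str,
    target_orientation: float,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Stimulus-driven and goal-driven gain fields for a model variant."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}; expected one of {VARIANTS}")
    if variant == "fs":
        ax = stimulus_attention_fs(components, grid, params.w_x, params.p)
    elif variant == "es":
        ax = stimulus_attention_es(components, grid, params.w_x, params.p)
    else:  # compound: FS and ES fields combine multiplicatively
        w_eye = params.w_x_eye if params.w_x_eye is not None else 0.0
        fs = stimulus_attention_fs(components, grid, params.w_x, params.p)
        es = stimulus_attention_es(components, grid, w_eye, params.p)
        ax = {eye: fs[eye] * es[eye] for eye in fs}
    av = goal_attention(target_orientation, grid, params.w_v)
    return ax, av


def population_response(
    e_fields: dict[str, np.ndarray],
    ax_fields: dict[str, np.ndarray],
    av_fields: dict[str, np.ndarray],
    params: ModelParams,
    grid: NeuronGrid,
    kernel: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Firing-rate fields R(x, theta) for both monocular populations.

    R_eye = (A_x A_v E_eye^n) / (S_eye + w S_other + sigma^n), where w is
    ``w_I`` or the directional weight for that population.
    """
    params.validate()
    if kernel is None:
        kernel = suppression_kernel(grid)
    drive_pow = {eye: e_fields[eye] ** params.n for eye in ("left", "right")}
    S = {
        eye: suppressive_drive(drive_pow[eye], ax_fields[eye], av_fields[eye], kernel, grid)
        for eye in ("left", "right")
    }
    out = {}
    for eye in ("left", "right"):
        other = "right" if eye == "left" else "left"
        w = params.interocular_weight(eye)
        denom = S[eye] + w * S[other] + params.sigma ** params.n
        R = ax_fields[eye] * av_fields[eye] * drive_pow[eye] / denom
        if not np.all(np.isfinite(R)):
            raise FloatingPointError("non-finite population response; check parameters")
        out[eye] = R
    return out


def predict_dprime(
    responses: dict[str, np.ndarray],
    target: StimulusComponent,
    params: ModelParams,
    grid: NeuronGrid,
) -> float:
    """Behavioral sensitivity from the neuron best matched to the target."""
    if params.sigma_n <= 0:
        raise ValueError("sigma_n must be positive")
    ix, it = grid.index_of(target.center_x, target.orientation)
    return float(responses[target.eye][ix, it] / params.sigma_n)


def _condition_dprime_field_engine(
    cond: Condition,
    params: ModelParams,
    variant: str,
    grid: NeuronGrid,
    kernel: np.ndarray,
    competitor_contrast: float,
) -> float:
    components = expand_condition(cond, competitor_contrast)
    target = components[0]
    e = excitatory_drive(components, grid)
    ax, av = attention_fields(components, grid, params, variant, target.orientation)
    resp = population_response(e, ax, av, params, grid, kernel=kernel)
    return predict_dprime(resp, target, params, grid)


def predict_psychometric(
    params: ModelParams,
    variant: str,
    conditions,
    contrasts,
    grid: NeuronGrid | None = None,
    target_eye: str = "right",
    competitor_contrast: float = 0.23,
    engine: str = "point",
):
    """Predicted d' for every (condition, target contrast) cell.

    ``conditions`` is a sequence of condition names (or ``(name, target_eye)``
    pairs).  The default ``point`` engine evaluates the suppressive drive only
    at the target neuron, which is exact and fast; ``field`` computes the full
    response fields and reads out the same neuron (reference path).

    Returns a tidy DataFrame with columns condition, target_eye, contrast,
    dprime.
    """
    import pandas as pd

    if grid is None:
        grid = NeuronGrid()
    conds = [c if isinstance(c, tuple) else (c, target_eye) for c in conditions]
    contrasts = np.asarray(contrasts, dtype=float)
    if engine == "point":
        pred = PsychometricPredictor(
            conds, contrasts, grid=grid, variant=variant,
            competitor_contrast=competitor_contrast,
        )
        dmat = pred.dprime(params)
    elif engine == "field":
        kernel = suppression_kernel(grid)
        dmat = np.empty((len(conds), contrasts.size))
        for i, (name, eye) in enumerate(conds):
            for j, c in enumerate(contrasts):
                dmat[i, j] = _condition_dprime_field_engine(
                    Condition(name, float(c), eye), params, variant, grid,
                    kernel, competitor_contrast,
                )
    else:
        raise ValueError(f"unknown engine {engine!r}")
    rows = []
    for i, (name, eye) in enumerate(conds):
        for j, c in enumerate(contrasts):
            rows.append((name, eye, float(c), dmat[i, j]))
    return pd.DataFrame(rows, columns=["condition", "target_eye", "contrast", "dprime"])


# ---------------------------------------------------------------------------
# fast point predictor
# ---------------------------------------------------------------------------

class PsychometricPredictor:
    """Precomputed d' predictor for a fixed design (conditions x contrasts).

    Exploits two structural facts: d' depends on the response of a single
    neuron, so the suppressive drive is needed only at one point (a weighted
    sum with a fixed kernel slice rather than a full convolution); and for an
    eye stimulated by a single component the drive E^n factors as
    c^n * g(x)^n h(theta)^n, so the contrast dependence is a scalar.  Only the
    split condition, whose target eye carries two components, requires a full
    per-contrast field power.

    The heavy geometry (drive profiles, kernel slice, attention profiles) is
    computed once at construction; :meth:`dprime` then evaluates the full
    design for one parameter vector in a fraction of a millisecond.
    """

    def __init__(
        self,
        conditions,
        contrasts,
        grid: NeuronGrid | None = None,
        variant: str = "fs",
        competitor_contrast: float = 0.23,
    ) -> None:
        if variant not in VARIANTS:
            raise ValueError(
                f"unknown model variant {variant!r}; expected one of {VARIANTS}"
            )
        self.grid = grid if grid is not None else NeuronGrid()
        self.variant = variant
        self.contrasts = np.asarray(contrasts, dtype=float)
        self.competitor_contrast = float(competitor_contrast)
        self.conditions = [
            c if isinstance(c, tuple) else (c, "right") for c in conditions
        ]
        g = self.grid
        self._theta_feat_comp = None
        self._cond_data = []
        kernel = suppression_kernel(g)
        for name, eye in self.conditions:
            cond = Condition(name, 1.0, eye)
            components = expand_condition(cond, self.competitor_contrast)
            target = components[0]
            ix, it = g.index_of(target.center_x, target.orientation)
            # kernel slice K(x_t - x', theta_t - theta') on the neuron grid
            nx = g.x.size
            offs = kernel_theta_offsets(g)
            j0 = int(np.argmin(np.abs(offs)))
            xi = (ix - np.arange(nx)) + (nx - 1)
            tj = np.array(
                [j0 + int(round(wrap_orientation(g.theta[it] - t) / g.dtheta)) % offs.size
                 for t in g.theta]
            ) % offs.size
            ksl = kernel[np.ix_(xi, tj)]
            per_eye = {"left": [], "right": []}
            for comp in components:
                gx = spatial_overlap(g.x, comp, g.rf_sd)
                ht = orientation_tuning(g.theta, comp.orientation, g.tuning_sd)
                per_eye[comp.eye].append(
                    {
                        "gx": gx,
                        "ht": ht,
                        "contrast": None if comp.role == "target" else comp.contrast,
                        "width": comp.width,
                        "eye": comp.eye,
                        "role": comp.role,
                    }
                )
            comp_list = [c for c in components if c.role == "competitor"]
            fused = fused_competitor_width(components)
            cond_info = {
                "name": name,
                "target_eye": eye,
                "point": (ix, it),
                "ksl": ksl,
                "per_eye": per_eye,
                "fused_width": fused,
                "theta_a": comp_list[0].orientation if comp_list else None,
                "es_comps": [(c.eye, c.width) for c in comp_list],
                "target_orientation": target.orientation,
            }
            # fixed spatial/orientation attention profiles (p-independent parts)
            if fused is not None:
                cond_info["exp_fs"] = np.exp(-(g.x ** 2) / (2.0 * fused ** 2))
                cond_info["at_fs"] = np.asarray(
                    feature_profile(g.theta - cond_info["theta_a"])
                )
                cond_info["exp_es"] = {
                    w: np.exp(-(g.x ** 2) / (2.0 * w ** 2))
                    for _, w in cond_info["es_comps"]
                }
            cond_info["at_goal"] = np.asarray(
                feature_profile(g.theta - target.orientation)
            )
            cond_info["ax_goal"] = np.asarray(
                spatial_profile(g.x, 0.0, GOAL_SIGMA_AX, GOAL_P)
            )
            self._cond_data.append(cond_info)

    # -- attention field builders (vectors/matrices on the neuron grid) -----

    def _ax_fields(self, info: dict, params: ModelParams) -> dict[str, np.ndarray]:
        g = self.grid
        if info["fused_width"] is None:
            one = np.ones((g.x.size, 1))
            return {"left": one, "right": one}
        out: dict[str, np.ndarray] = {}
        if self.variant in ("fs", "compound"):
            scale = params.w_x * info["fused_width"] ** (-params.p) / _SQRT2PI
            fs = scale * info["exp_fs"][:, None] * info["at_fs"][None, :] + 1.0
            out = {"left": fs, "right": fs}
        if self.variant in ("es", "compound"):
            w = params.w_x if self.variant == "es" else (params.w_x_eye or 0.0)
            dev = {"left": np.zeros(g.x.size), "right": np.zeros(g.x.size)}
            for eye, width in info["es_comps"]:
                a = w * width ** (-params.p) / _SQRT2PI * info["exp_es"][width]
                dev[eye] += a
                dev["left" if eye == "right" else "right"] -= a
            es = {e: (1.0 + d)[:, None] for e, d in dev.items()}
            if self.variant == "es":
                out = es
            else:
                out = {e: out[e] * es[e] for e in es}
        return out

    def _av_field(self, info: dict, params: ModelParams) -> np.ndarray:
        return params.w_v * info["ax_goal"][:, None] * info["at_goal"][None, :] + 1.0

    def min_gain(self, params: ModelParams) -> float:
        """Smallest attentional gain over all conditions, eyes and sources.

        Uses the separable structure of the gain fields: the minimum of the
        feature profile is exp(-2k) - 0.5 at the orthogonal orientation and
        the spatial profiles peak at x = 0, so the minima are closed-form
        (FS, goal-driven) or a cheap 1-D scan (ES deviations).
        """
        at_min = float(np.exp(-2.0 * FEATURE_K) - 0.5)  # most negative profile value
        m = 1.0 + params.w_v * at_min / _SQRT2PI  # goal-driven, a_x peak (2 pi)^-1/2
        for info in self._cond_data:
            if info["fused_width"] is None:
                continue
            if self.variant in ("fs", "compound"):
                peak = params.w_x * info["fused_width"] ** (-params.p) / _SQRT2PI
                m = min(m, 1.0 + peak * at_min)
            if self.variant in ("es", "compound"):
                w = params.w_x if self.variant == "es" else (params.w_x_eye or 0.0)
                dev = np.zeros(self.grid.x.size)
                for eye, width in info["es_comps"]:
                    a = w * width ** (-params.p) / _SQRT2PI * info["exp_es"][width]
                    # the worst-off eye is the one losing gain from this
                    # component; track both signs via the envelope below
                    dev = dev + a if eye == "left" else dev - a
                m = min(m, 1.0 - float(np.abs(dev).max()))
        return m

    def gain_report(self, params: ModelParams):
        """Attentional gains at the target neuron, per condition.

        Mirrors the parenthesized values conventionally reported alongside the
        best-fit w_x and w_v: the stimulus-driven gain of the neuron tuned to
        the target (in the target eye) for each competitor configuration, and
        the (condition-independent) goal-driven gain.
        """
        import pandas as pd

        rows = []
        for info in self._cond_data:
            ix, it = info["point"]
            ax = self._ax_fields(info, params)[info["target_eye"]]
            av = self._av_field(info, params)
            ax_pt = float(ax[ix, 0] if ax.shape[1] == 1 else ax[ix, it])
            rows.append(
                (info["name"], ax_pt, float(av[ix, it]))
            )
        return pd.DataFrame(
            rows, columns=["condition", "stimulus_gain", "goal_gain"]
        )

    # -- d' evaluation -------------------------------------------------------

    def dprime(self, params: ModelParams) -> np.ndarray:
        """d' matrix of shape (n_conditions, n_contrasts)."""
        params.validate()
        g = self.grid
        n = params.n
        c = self.contrasts
        cn = c ** n
        area = g.cell_area
        out = np.empty((len(self._cond_data), c.size))
        for row, info in enumerate(self._cond_data):
            ix, it = info["point"]
            tgt_eye = info["target_eye"]
            ksl = info["ksl"]
            ax = self._ax_fields(info, params)
            av = self._av_field(info, params)
            S = {"left": None, "right": None}
            I_pt = None
            for eye in ("left", "right"):
                comps = info["per_eye"][eye]
                if not comps:
                    S[eye] = np.zeros(c.size)
                    continue
                M = ax[eye] * av  # broadcasts (nx,1) or (nx,nt) with (nx,nt)
                W = ksl * M
                if len(comps) == 1:
                    comp = comps[0]
                    gxn = comp["gx"] ** n
                    htn = comp["ht"] ** n
                    s_unit = float(gxn @ W @ htn) * area
                    if comp["contrast"] is None:
                        S[eye] = cn * s_unit
                        if eye == tgt_eye:
                            m_pt = float(M[ix, 0] if M.shape[1] == 1 else M[ix, it])
                            I_pt = cn * (m_pt * gxn[ix] * htn[it])
                    else:
                        fixed = comp["contrast"] ** n * s_unit
                        S[eye] = np.full(c.size, fixed)
                        if eye == tgt_eye:
                            raise RuntimeError("target eye without a target component")
                else:
                    # split-condition target eye: target + annular surround
                    bases = []
                    for comp in comps:
                        B = comp["gx"][:, None] * comp["ht"][None, :]
                        bases.append((comp["contrast"], B))
                    E = np.zeros((c.size,) + g.shape)
                    for contrast, B in bases:
                        if contrast is None:
                            E += c[:, None, None] * B[None, :, :]
                        else:
                            E += contrast * B[None, :, :]
                    F = E ** n
                    S[eye] = np.einsum("cij,ij->c", F, W) * area
                    if eye == tgt_eye:
                        m_pt = float(M[ix, 0] if M.shape[1] == 1 else M[ix, it])
                        I_pt = m_pt * F[:, ix, it]
            if I_pt is None:
                raise RuntimeError("condition without a target component")
            other = "right" if tgt_eye == "left" else "left"
            w = params.interocular_weight(tgt_eye)
            denom = S[tgt_eye] + w * S[other] + params.sigma ** n
            out[row] = I_pt / denom / params.sigma_n
        return out
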