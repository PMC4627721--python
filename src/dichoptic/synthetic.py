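"""Synthetic psychophysics data with the structure of the interocular
suppression study design.

The emulated experiment: four observers view a 45 deg target in one eye at
nine contrast levels while an orthogonal competitor (none / small / medium /
large / split) is shown at a fixed 23 % RMS contrast, with at least 50 trials
per cell.  Trial outcomes are Bernoulli draws with P(correct) = Phi(d'/2),
the exact inverse of the unbiased two-choice d' estimator used by the
analysis, where d' comes from the normalization model.  Trials are
independent: there are no sequential dependencies and, by default, no lapses
(a lapse rate is available for robustness checks).

Reference parameter sets collected here are published group and
per-observer best-fit values for this model family; they serve as generator
defaults so that synthetic cohorts show the empirically observed pattern of
individual differences (notably the wide spread of the interocular
normalization weight ``w_I``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .grid import NeuronGrid
from .population import ModelParams, PsychometricPredictor

__all__ = [
    "FS_GROUP_PARAMS",
    "ES_GROUP_PARAMS",
    "FS_PRIOR_STUDY_PARAMS",
    "ES_PRIOR_STUDY_PARAMS",
    "FS_OBSERVER_PARAMS",
    "StudyDesign",
    "default_contrasts",
    "default_design",
    "generate_trials",
    "generate_eye_swap_session",
]

#: group best fit of the feature-specific variant to the five-condition study
FS_GROUP_PARAMS = ModelParams(
    n=1.95, sigma=0.0016, w_I=0.67, w_x=4.24, w_v=5.03, p=0.13, sigma_n=2.92
)
#: group best fit of the eye-specific variant to the five-condition study
ES_GROUP_PARAMS = ModelParams(
    n=1.85, sigma=0.0016, w_I=1.08, w_x=2.46, w_v=4.90, p=0.71, sigma_n=2.82
)
#: best fits to the earlier four-condition (no split competitor) data set
FS_PRIOR_STUDY_PARAMS = ModelParams(
    n=2.16, sigma=0.0020, w_I=0.80, w_x=4.70, w_v=5.03, p=0.17, sigma_n=3.11
)
ES_PRIOR_STUDY_PARAMS = ModelParams(
    n=2.01, sigma=0.0019, w_I=0.80, w_x=2.41, w_v=4.99, p=0.31, sigma_n=2.95
)
#: per-observer feature-specific best fits; note the heterogeneous w_I
FS_OBSERVER_PARAMS: dict[str, ModelParams] = {
    "S1": ModelParams(n=2.15, sigma=0.0019, w_I=0.01, w_x=4.62, w_v=4.65, p=0.26, sigma_n=3.10),
    "S2": ModelParams(n=2.21, sigma=0.0018, w_I=1.08, w_x=4.50, w_v=5.03, p=0.20, sigma_n=3.26),
    "S3": ModelParams(n=1.67, sigma=0.0014, w_I=1.15, w_x=2.96, w_v=5.02, p=0.24, sigma_n=2.49),
    "S4": ModelParams(n=2.22, sigma=0.0016, w_I=3.81, w_x=4.89, w_v=5.03, p=0.12, sigma_n=3.18),
}

ALL_CONDITIONS = ("none", "small", "medium", "large", "split")
EYE_SWAP_CONDITIONS = ("none", "large", "split")


def default_contrasts(n_levels: int = 9, lo: float = 0.003, hi: float = 0.35) -> np.ndarray:
    """Nine log-spaced target contrasts from 0.3 % to 35 % RMS."""
    return np.geomspace(lo, hi, n_levels)


@dataclass(frozen=True)
class StudyDesign:
    """Layout of a synthetic session: who sees what, how often."""

    observers: dict[str, ModelParams]
    conditions: tuple[str, ...] = ALL_CONDITIONS
    contrasts: np.ndarray = field(default_factory=default_contrasts)
    trials_per_cell: int = 50
    competitor_contrast: float = 0.23
    target_eye: str = "right"
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.trials_per_cell < 1:
            raise ValueError("trials_per_cell must be >= 1")
        if not 0.0 <= self.lapse_rate < 1.0:
            raise ValueError("lapse_rate must lie in [0, 1)")
        if not self.observers:
            raise ValueError("at least one observer is required")

    @property
    def n_cells(self) -> int:
        return len(self.observers) * len(self.conditions) * len(self.contrasts)


def default_design(trials_per_cell: int = 50) -> StudyDesign:
    """The four-observer, five-condition, nine-contrast reference design."""
    return StudyDesign(observers=dict(FS_OBSERVER_PARAMS), trials_per_cell=trials_per_cell)


def predicted_dprime_table(
    design: StudyDesign, variant: str = "fs", grid: NeuronGrid | None = None
) -> pd.DataFrame:
    """Model d' for every cell of a design (no noise)."""
    conds = [(c, design.target_eye) for c in design.conditions]
    rows = []
    pred = PsychometricPredictor(
        conds, design.contrasts, grid=grid, variant=variant,
        competitor_contrast=design.competitor_contrast,
    )
    for obs, params in design.observers.items():
        dmat = pred.dprime(params)
        for i, cond in enumerate(design.conditions):
            for j, c in enumerate(design.contrasts):
                rows.append((obs, cond, design.target_eye, float(c), dmat[i, j]))
    return pd.DataFrame(
        rows, columns=["observer", "condition", "target_eye", "contrast", "dprime"]
    )


def generate_trials(
    design: StudyDesign,
    variant: str = "fs",
    seed: int | None = 0,
    grid: NeuronGrid | None = None,
) -> pd.DataFrame:
    """Simulate a trial table from the normalization model.

    P(correct) = Phi(d'/2) per cell (mixed with chance at the design's lapse
    rate); outcomes are independent Bernoulli draws.  Reproducible: each
    observer gets a child seed spawned from the master seed, and cells are
    drawn in a fixed order.
    """
    dtab = predicted_dprime_table(design, variant=variant, grid=grid)
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(design.observers))
    frames = []
    for child, (obs, sub) in zip(children, dtab.groupby("observer", sort=False)):
        rng = np.random.default_rng(child)
        sub = sub.reset_index(drop=True)
        for _, row in sub.iterrows():
            p = ndtr(row.dprime / 2.0)
            p = design.lapse_rate * 0.5 + (1.0 - design.lapse_rate) * p
            correct = rng.random(design.trials_per_cell) < p
            frames.append(
                pd.DataFrame(
                    {
                        "observer": obs,
                        "condition": row.condition,
                        "target_eye": row.target_eye,
                        "contrast": row.contrast,
                        "trial": np.arange(design.trials_per_cell),
                        "correct": correct.astype(int),
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    out.attrs["seed"] = seed
    out.attrs["variant"] = variant
    return out


def generate_eye_swap_session(
    design: StudyDesign,
    variant: str = "fs",
    seed: int | None = 0,
    grid: NeuronGrid | None = None,
) -> pd.DataFrame:
    """Sessions with target and competitor eyes swapped.

    Only the three conditions informative about eye-of-origin (none, large,
    split) are run, with the target in the left eye.  Directional
    interocular weights (w_LR / w_RL on the observers' parameters) make the
    two sessions differ; with symmetric weights the swap is a relabeling.
    """
    swapped = replace(
        design,
        conditions=EYE_SWAP_CONDITIONS,
        target_eye="left" if design.target_eye == "right" else "right",
    )
    return generate_trials(swapped, variant=variant, seed=seed, grid=grid)
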