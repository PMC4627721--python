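"""Parametric description of the dichoptic stimuli.

Each trial presents a small oriented target patch to one eye and, depending on
the condition, an orthogonally oriented competitor to the other eye.  The five
competitor configurations are

``none``
    target alone,
``small`` / ``medium`` / ``large``
    a 1.5 / 2.5 / 8 deg competitor in the non-target eye,
``split``
    the large competitor segmented into a 1.5 deg center shown to the
    non-target eye plus an annular surround (1.5-8 deg) shown to the *target*
    eye; when fused the two parts look identical to the large competitor.

Stimuli are represented parametrically on a single spatial axis: a component
is an interval (or annulus) of given width centered at ``center_x`` carrying a
single orientation and an RMS contrast.  No pixel rendering is performed; the
10 deg orientation bandwidth of the noise carrier is absorbed into the
neuronal tuning width (see :mod:`dichoptic.population`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

TARGET_ORIENTATION = 45.0
COMPETITOR_ORIENTATION = 135.0
TARGET_WIDTH = 1.5
#: default competitor RMS contrast, fixed across all trials of the study design
COMPETITOR_CONTRAST = 0.23

#: outer diameter (deg) of the competitor for each condition
COMPETITOR_WIDTHS: dict[str, float | None] = {
    "none": None,
    "small": 1.5,
    "medium": 2.5,
    "large": 8.0,
    "split": 8.0,
}

CONDITION_NAMES = tuple(COMPETITOR_WIDTHS)

_EYES = ("left", "right")


def other_eye(eye: str) -> str:
    if eye not in _EYES:
        raise ValueError(f"unknown eye label {eye!r}; expected 'left' or 'right'")
    return "right" if eye == "left" else "left"


@dataclass(frozen=True)
class StimulusComponent:
    """One monocular patch.

    ``width`` is the outer aperture diameter; a positive ``inner_width`` turns
    the aperture into an annulus (used for the surround of the split
    competitor).  Apertures are hard intervals; the Gaussian receptive field
    already smooths their edges.
    """

    eye: str
    orientation: float
    center_x: float
    width: float
    contrast: float
    inner_width: float = 0.0
    role: str = "target"

    def __post_init__(self) -> None:
        if self.eye not in _EYES:
            raise ValueError(f"unknown eye label {self.eye!r}")
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.contrast < 0:
            raise ValueError("contrast must be non-negative")
        if not 0 <= self.inner_width < self.width:
            raise ValueError("inner_width must lie in [0, width)")
        if self.role not in ("target", "competitor"):
            raise ValueError(f"unknown component role {self.role!r}")
        object.__setattr__(self, "orientation", float(self.orientation) % 180.0)

    def swap_eye(self) -> "StimulusComponent":
        return replace(self, eye=other_eye(self.eye))


@dataclass(frozen=True)
class Condition:
    """A competitor configuration at one target contrast."""

    name: str
    target_contrast: float
    target_eye: str = "right"

    def __post_init__(self) -> None:
        if self.name not in COMPETITOR_WIDTHS:
            raise ValueError(
                f"unknown condition name {self.name!r}; "
                f"expected one of {CONDITION_NAMES}"
            )
        if self.target_contrast < 0:
            raise ValueError("target_contrast must be non-negative")
        if self.target_eye not in _EYES:
            raise ValueError(f"unknown eye label {self.target_eye!r}")


def expand_condition(
    cond: Condition, competitor_contrast: float = COMPETITOR_CONTRAST
) -> list[StimulusComponent]:
    """Expand a condition into its per-eye component list.

    The target (1.5 deg, 45 deg orientation) always goes to ``target_eye``.
    Competitors are orthogonal (135 deg) and centered at x = 0.  For the split
    condition the 1.5 deg center goes to the competitor eye and the annular
    surround (1.5-8 deg) goes to the target eye, both at the competitor
    contrast, so that the union of split apertures equals the large
    competitor's aperture.
    """
    comp_eye = other_eye(cond.target_eye)
    target = StimulusComponent(
        eye=cond.target_eye,
        orientation=TARGET_ORIENTATION,
        center_x=0.0,
        width=TARGET_WIDTH,
        contrast=cond.target_contrast,
        role="target",
    )
    if cond.name == "none":
        return [target]
    width = COMPETITOR_WIDTHS[cond.name]
    if cond.name == "split":
        center = StimulusComponent(
            eye=comp_eye,
            orientation=COMPETITOR_ORIENTATION,
            center_x=0.0,
            width=TARGET_WIDTH,
            contrast=competitor_contrast,
            role="competitor",
        )
        surround = StimulusComponent(
            eye=cond.target_eye,
            orientation=COMPETITOR_ORIENTATION,
            center_x=0.0,
            width=width,
            inner_width=TARGET_WIDTH,
            contrast=competitor_contrast,
            role="competitor",
        )
        return [target, center, surround]
    competitor = StimulusComponent(
        eye=comp_eye,
        orientation=COMPETITOR_ORIENTATION,
        center_x=0.0,
        width=width,
        contrast=competitor_contrast,
        role="competitor",
    )
    return [target, competitor]


def swap_eyes(components: list[StimulusComponent]) -> list[StimulusComponent]:
    """Mirror every component's eye label (an involution)."""
    return [c.swap_eye() for c in components]


def fused_competitor_width(components: list[StimulusComponent]) -> float | None:
    """Outer extent of the fused (cyclopean) competitor, or None if absent."""
    widths = [c.width for c in components if c.role == "competitor"]
    return max(widths) if widths else None
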