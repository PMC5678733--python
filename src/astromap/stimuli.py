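"""Retinal training and probe stimuli.

Training inputs are elongated 2-D Gaussians with centres and orientations
drawn uniformly at random; probe inputs are full-field sine gratings used to
measure orientation preference with plasticity frozen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import StimulusParams
from .geometry import SheetGeometry


@dataclass(frozen=True)
class TrainingStimulus:
    """One elongated-Gaussian training pattern.

    ``orientation`` is the angle of the major axis, folded to [0, pi).
    """

    center: tuple[float, float]  # (x, y) sheet units
    orientation: float  # radians in [0, pi)
    sigma_major: float
    sigma_minor: float
    amplitude: float

    def __post_init__(self) -> None:
        if not (self.sigma_major >= self.sigma_minor > 0):
            raise ValueError("need sigma_major >= sigma_minor > 0")


def sample_training_stimulus(
    rng: np.random.Generator,
    geometry: SheetGeometry,
    params: StimulusParams,
) -> TrainingStimulus:
    """Draw a training stimulus with uniform random centre and orientation.

    The centre is uniform over the retinal extent widened by ``params.margin``
    on each side, so stimuli may straddle the sheet edge.  Deterministic
    given the generator state.
    """
    params.validate()
    half = geometry.extent / 2.0 + params.margin
    cx, cy = rng.uniform(-half, half, size=2)
    theta = rng.uniform(0.0, np.pi) % np.pi
    return TrainingStimulus(
        center=(float(cx), float(cy)),
        orientation=float(theta),
        sigma_major=params.sigma_major,
        sigma_minor=params.sigma_minor,
        amplitude=params.amplitude,
    )


def render_stimulus(stim: TrainingStimulus, geometry: SheetGeometry) -> np.ndarray:
    """Rasterize a stimulus onto the retinal sheet.

    The value at node ``u`` is
    ``amplitude * exp(-(d_maj^2 / (2 s_maj^2) + d_min^2 / (2 s_min^2)))``
    where ``(d_maj, d_min)`` are the coordinates of ``u - center`` rotated by
    ``-orientation``; the peak equals ``amplitude`` at the centre.
    """
    x, y = geometry.coords()
    dx = x - stim.center[0]
    dy = y - stim.center[1]
    c, s = np.cos(stim.orientation), np.sin(stim.orientation)
    d_major = c * dx + s * dy
    d_minor = -s * dx + c * dy
    field = stim.amplitude * np.exp(
        -(
            d_major**2 / (2.0 * stim.sigma_major**2)
            + d_minor**2 / (2.0 * stim.sigma_minor**2)
        )
    )
    return field


def render_grating(
    geometry: SheetGeometry,
    orientation: float,
    spatial_freq: float,
    phase: float = 0.0,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Full-field sinusoidal grating on the retinal sheet.

    ``orientation`` is the angle of the *stripes* (so the wave vector is
    perpendicular to it); ``spatial_freq`` is in cycles per sheet unit.  The
    grating is rendered on a mid-level pedestal, ``A/2 * (1 + cos(...))``,
    so retinal activity stays non-negative.
    """
    x, y = geometry.coords()
    kx = -np.sin(orientation) * 2.0 * np.pi * spatial_freq
    ky = np.cos(orientation) * 2.0 * np.pi * spatial_freq
    return amplitude * 0.5 * (1.0 + np.cos(kx * x + ky * y + phase))


def principal_axis_angle(field: np.ndarray, geometry: SheetGeometry) -> float:
    """Orientation of a field's principal second-moment axis, in [0, pi).

    Image-moment estimate used as an independent check on rendered stimulus
    orientation.
    """
    x, y = geometry.coords()
    total = field.sum()
    if total <= 0:
        raise ValueError("field has no mass")
    mx = (field * x).sum() / total
    my = (field * y).sum() / total
    mxx = (field * (x - mx) ** 2).sum() / total
    myy = (field * (y - my) ** 2).sum() / total
    mxy = (field * (x - mx) * (y - my)).sum() / total
    return float(0.5 * np.arctan2(2.0 * mxy, mxx - myy) % np.pi)
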