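"""ON/OFF LGN stage: difference-of-Gaussians filtering with lateral gain control.

Each LGN channel filters retinal activity with a zero-sum centre-surround
kernel and is then gain-controlled by a suppressive pool of neighbouring LGN
units, settled over a short recursion each presentation.  The retinal sheet
is larger than the LGN sheet by exactly the kernel support, so the afferent
convolution is computed in 'valid' mode with no edge padding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .config import LGNParams
from .geometry import SheetGeometry

ON, OFF = "ON", "OFF"


@dataclass(frozen=True)
class DoGKernel:
    """Difference-of-Gaussians receptive field.

    Both Gaussians are normalised to unit mass over the discrete support, so
    kernel entries sum to zero and the response to a uniform field vanishes.
    The OFF kernel is the exact negation of the ON kernel.
    """

    center_sigma: float
    surround_sigma: float
    support_radius: float
    weights: np.ndarray
    polarity: str

    @property
    def half_width(self) -> int:
        return (self.weights.shape[0] - 1) // 2


def _unit_gaussian(sigma_px: float, h: int) -> np.ndarray:
    ax = np.arange(-h, h + 1, dtype=float)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    g = np.exp(-(xx**2 + yy**2) / (2.0 * sigma_px**2))
    return g / g.sum()


def make_dog_kernel(
    sigma_c: float,
    sigma_s: float,
    support_radius: float,
    density: int,
    polarity: str = ON,
) -> DoGKernel:
    """Build a DoG kernel on a sheet of the given density.

    Sigmas and support are in sheet units.  A support radius below three
    surround sigmas triggers a truncation warning.
    """
    if not (sigma_s > sigma_c > 0):
        raise ValueError("need sigma_s > sigma_c > 0")
    if polarity not in (ON, OFF):
        raise ValueError(f"polarity must be {ON!r} or {OFF!r}")
    if support_radius < 3.0 * sigma_s:
        warnings.warn(
            f"DoG support radius {support_radius} < 3 * sigma_s = {3 * sigma_s}: "
            "surround truncation may be significant",
            stacklevel=2,
        )
    h = int(round(support_radius * density))
    center = _unit_gaussian(sigma_c * density, h)
    surround = _unit_gaussian(sigma_s * density, h)
    weights = center - surround
    if polarity == OFF:
        weights = -weights
    return DoGKernel(sigma_c, sigma_s, support_radius, weights, polarity)


def make_pool_kernel(sigma_pool: float, support_radius: float, density: int) -> np.ndarray:
    """Unit-mass Gaussian kernel for the suppressive LGN pool."""
    h = max(1, int(round(support_radius * density)))
    return _unit_gaussian(sigma_pool * density, h)


def dog_transfer_peak(sigma_c: float, sigma_s: float) -> float:
    """Spatial frequency (cycles/sheet unit) maximising the DoG transfer.

    Closed form from the Fourier transform of a difference of unit-mass
    Gaussians: ``f* = sqrt(ln(s_s^2 / s_c^2) / (2 pi^2 (s_s^2 - s_c^2)))``.
    """
    num = np.log(sigma_s**2 / sigma_c**2)
    den = 2.0 * np.pi**2 * (sigma_s**2 - sigma_c**2)
    return float(np.sqrt(num / den))


@dataclass
class LGNState:
    """Rectified ON and OFF channel activities on the LGN sheet."""

    on: np.ndarray
    off: np.ndarray

    def __post_init__(self) -> None:
        if self.on.shape != self.off.shape:
            raise ValueError("ON and OFF fields must share a shape")


class LGNStage:
    """Bundles the DoG kernels, pool kernel and gain-control parameters."""

    def __init__(self, params: LGNParams, retina: SheetGeometry, lgn: SheetGeometry):
        params.validate()
        self.params = params
        self.retina = retina
        self.lgn = lgn
        self.kernel_on = make_dog_kernel(
            params.sigma_c, params.sigma_s, params.effective_support, retina.density, ON
        )
        self.kernel_off = make_dog_kernel(
            params.sigma_c, params.sigma_s, params.effective_support, retina.density, OFF
        )
        self.pool = make_pool_kernel(
            params.effective_sigma_pool, params.effective_support, lgn.density
        )
        expected = lgn.n + 2 * self.kernel_on.half_width
        if retina.n != expected:
            raise ValueError(
                f"retina has {retina.n} nodes/axis but {expected} are required "
                f"for a valid-mode afferent convolution onto {lgn.n} LGN nodes"
            )

    # -- single recursion step --------------------------------------------

    def _afferent(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if x.shape != self.retina.shape:
            raise ValueError(f"retinal field shape {x.shape} != {self.retina.shape}")
        aff_on = fftconvolve(x, self.kernel_on.weights, mode="valid")
        return aff_on, -aff_on  # OFF kernel is the exact negation

    def _step_from_aff(
        self, aff: tuple[np.ndarray, np.ndarray], prev: LGNState
    ) -> LGNState:
        p = self.params
        out = []
        for a, l_prev in zip(aff, (prev.on, prev.off)):
            pooled = fftconvolve(l_prev, self.pool, mode="same")
            if p.gain_mode == "divisive":
                drive = p.gamma_o * a / (1.0 + p.gamma_s * pooled)
            else:
                drive = p.gamma_o * a - p.gamma_s * pooled
            out.append(np.maximum(drive, 0.0))
        return LGNState(on=out[0], off=out[1])

    def step(self, x: np.ndarray, prev: LGNState) -> LGNState:
        """One step of the LGN recursion (both channels).

        Afferent drive is the valid-mode DoG convolution of the retinal
        field; the suppressive pool of each channel's previous activity then
        acts divisively (gain control) or subtractively, followed by
        half-wave rectification.  Deterministic.
        """
        return self._step_from_aff(self._afferent(x), prev)

    def settle(self, x: np.ndarray) -> LGNState:
        """Settled LGN response to a retinal field.

        Starts from the pure rectified afferent response and applies
        ``settle_steps`` recursion steps so the pool becomes effective.
        The afferent convolution is computed once (the stimulus is fixed
        during settling).
        """
        aff = self._afferent(x)
        zeros = LGNState(np.zeros(self.lgn.shape), np.zeros(self.lgn.shape))
        state = self._step_from_aff(aff, zeros)
        for _ in range(self.params.settle_steps):
            state = self._step_from_aff(aff, state)
        return state


def lgn_step(
    x: np.ndarray,
    prev: LGNState,
    stage: LGNStage,
) -> LGNState:
    """Functional wrapper around :meth:`LGNStage.step`."""
    return stage.step(x, prev)
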