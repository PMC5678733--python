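"""Astrocyte layer: disc pooling of synaptic drive, gap junctions, normalisation.

Each astrocyte node pools the synaptic drive ``gs`` of every V1 node within
Euclidean distance ``R_astro`` of it.  The pooled activation is rescaled
into [0, 1] by a slowly tracked running maximum, so that the BCM threshold
``theta = 1 - S`` is well defined.  Optionally, fixed Gaussian-random gap
junction weights couple each astrocyte to its 8 nearest neighbours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import convolve2d

from .config import AstrocyteParams
from .geometry import SheetGeometry
from .projections import circular_mask, extract_patches


@dataclass
class AstrocyteState:
    """Normalised astrocyte activation and its bookkeeping."""

    S: np.ndarray  # normalised activation in [0, 1]
    S_raw: np.ndarray  # pooled synaptic drive before normalisation
    radius_mm: float  # effective (GFAP-scaled) pooling radius
    running_max: float


def disc_pool(gs: np.ndarray, radius_px: float) -> np.ndarray:
    """Sum ``gs`` over all nodes within ``radius_px`` of each node.

    The disc always contains the pooling node itself, so a sub-pixel radius
    reduces to identity pooling.  Off-sheet neighbours contribute zero.
    Contributions are accumulated over disc offsets in row-major order, so
    the result is bit-for-bit the sequential per-node sum.
    """
    h = int(np.floor(radius_px))
    if h == 0:
        return gs.copy()
    n0, n1 = gs.shape
    padded = np.pad(gs, h)
    out = np.zeros_like(gs)
    for di in range(-h, h + 1):
        for dj in range(-h, h + 1):
            if di * di + dj * dj <= radius_px**2 + 1e-9:
                out += padded[h + di : h + di + n0, h + dj : h + dj + n1]
    return out


def make_gap_junction_kernel(
    rng: np.random.Generator, strength: float, sigma: float
) -> np.ndarray:
    """Fixed random gap-junction kernel to the 8 nearest neighbours.

    Weights are magnitudes of N(0, sigma) draws, rescaled so their total is
    exactly ``strength``; the centre entry is zero.  Drawn once at model
    initialisation and fixed thereafter.
    """
    k = np.abs(rng.normal(0.0, sigma, size=(3, 3)))
    k[1, 1] = 0.0
    total = k.sum()
    if strength <= 0 or total == 0:
        return np.zeros((3, 3))
    return k * (strength / total)


def gap_junction_update(S: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Diffuse activation through gap junctions and renormalise.

    ``S' = S + kernel (*) S``, rescaled by its maximum when that exceeds 1
    so the activation stays in [0, 1].  A zero kernel leaves S unchanged.
    """
    if kernel.shape != (3, 3):
        raise ValueError("gap-junction kernel must be 3x3")
    if not np.any(kernel):
        return S
    out = S + convolve2d(S, kernel, mode="same")
    peak = out.max()
    if peak > 1.0:
        out = out / peak
    return out


class AstrocyteLayer:
    """Stateful astrocyte sheet bound to a cortical geometry."""

    def __init__(
        self,
        params: AstrocyteParams,
        geometry: SheetGeometry,
        rng: np.random.Generator | None = None,
    ):
        params.validate()
        self.params = params
        self.geometry = geometry
        self.radius_px = geometry.to_pixels(
            geometry.mm_to_sheet(params.scaled_radius_mm)
        )
        if self.radius_px < 1.0:
            warnings.warn(
                f"astrocyte pooling radius {params.scaled_radius_mm} mm is below one "
                f"node spacing ({geometry.sheet_to_mm(geometry.spacing)} mm at density "
                f"{geometry.density}); pooling degenerates to single-node "
                "(increase density to resolve smaller radii)",
                stacklevel=2,
            )
        self.running_max = 0.0
        if params.gap_junctions:
            if rng is None:
                raise ValueError("gap junctions require an rng at construction")
            self.gap_kernel = make_gap_junction_kernel(
                rng, params.gap_strength, params.gap_sigma
            )
        else:
            self.gap_kernel = None

    def activate(self, gs: np.ndarray, update_norm: bool = True) -> AstrocyteState:
        """Pool synaptic drive and normalise into [0, 1].

        Under ``norm_mode='presentation'`` (default) each presentation is
        normalised by its own peak, so every stimulus defines a maximally
        activated astrocytic domain; ``norm_mode='running'`` instead divides
        by a running maximum that rises immediately to any new peak and
        relaxes toward the current peak with time constant ``norm_tau``
        presentations.  With ``update_norm=False`` (probing) stored
        normaliser state is not updated.
        """
        raw = disc_pool(gs, self.radius_px)
        if self.gap_kernel is not None:
            raw = raw + convolve2d(raw, self.gap_kernel, mode="same")
        peak = float(raw.max(initial=0.0))
        if self.params.norm_mode == "presentation":
            m = peak
        else:
            m = self.running_max
            if update_norm:
                alpha = 1.0 / self.params.norm_tau
                m = max(peak, (1.0 - alpha) * m + alpha * peak)
                self.running_max = m
            else:
                m = max(m, peak)
        if m <= 0:
            S = np.zeros_like(raw)
        else:
            S = np.clip(raw / m, 0.0, 1.0)
        return AstrocyteState(
            S=S,
            S_raw=raw,
            radius_mm=self.params.scaled_radius_mm,
            running_max=self.running_max,
        )
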