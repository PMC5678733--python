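"""Per-unit connection fields and their plasticity rules.

Every cortical unit owns a weight kernel over a circular support for each of
its projections: afferent (A, from the ON and OFF LGN channels jointly),
lateral excitatory (E) and lateral inhibitory (I).  Kernels are stored as a
dense ``(n_units, n_support)`` matrix over the flattened circular support,
and activity patches are extracted with the same layout, so drives and
weight updates are plain row-wise contractions.

Afferent and inhibitory kernels learn with the divisively normalised Hebbian
rule (each unit's kernel sums to 1 after every update).  Lateral excitatory
kernels learn with an astrocyte-thresholded BCM rule and are clipped to
``[0, e_max]`` instead of being renormalised: synapses whose postsynaptic
unit sits below the astrocytic threshold are driven to zero and pruned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .geometry import SheetGeometry

AFFERENT, EXCITATORY, INHIBITORY = "A", "E", "I"


def circular_mask(radius_px: float, half_width: int | None = None) -> np.ndarray:
    """Boolean disc of the given pixel radius on a (2h+1)^2 grid.

    The centre node is always inside the disc, so a sub-pixel radius yields
    single-node support.
    """
    h = int(np.floor(radius_px)) if half_width is None else half_width
    h = max(h, 0)
    ax = np.arange(-h, h + 1)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    return (xx**2 + yy**2) <= radius_px**2 + 1e-9


def extract_patches(
    field_2d: np.ndarray, half_width: int, mask_flat: np.ndarray, valid: bool = False
) -> np.ndarray:
    """Per-target-unit activity patches over the flattened circular support.

    With ``valid=False`` the field is zero-padded by ``half_width`` so each
    unit of the same sheet sees its neighbourhood; with ``valid=True`` the
    field must already be larger than the target sheet by ``2 * half_width``
    (the afferent case).  Returns ``(n_units, n_support)``.
    """
    k = 2 * half_width + 1
    src = field_2d if valid else np.pad(field_2d, half_width)
    win = sliding_window_view(src, (k, k))
    n_units = win.shape[0] * win.shape[1]
    return win.reshape(n_units, k * k)[:, mask_flat]


@dataclass
class ProjectionField:
    """Weight kernels of one projection for every target unit."""

    kind: str
    radius: float  # sheet units
    half_width: int
    mask: np.ndarray  # (k, k) bool
    weights: np.ndarray  # (n_units, n_channels * n_support)
    n_channels: int = 1
    normalized: bool = True  # divisively renormalised after each update
    e_max: float = field(default=np.inf)

    @property
    def n_support(self) -> int:
        return int(self.mask.sum())

    @property
    def mask_flat(self) -> np.ndarray:
        return self.mask.ravel()

    def drive(self, patches: np.ndarray) -> np.ndarray:
        """Row-wise contraction of weights with activity patches."""
        return np.einsum("ns,ns->n", self.weights, patches)

    def _dense(self) -> np.ndarray:
        """Per-unit kernels as a dense (n_units, C, k, k) array, cached.

        The cache is keyed on the identity of ``weights`` — every learning
        rule returns a fresh array, so mutation in place is not supported.
        """
        cached = getattr(self, "_dense_cache", None)
        if cached is not None and cached[0] is self.weights:
            return cached[1]
        k = 2 * self.half_width + 1
        n = self.weights.shape[0]
        dense = np.zeros((n, self.n_channels, k * k))
        dense[:, :, self.mask_flat] = self.weights.reshape(n, self.n_channels, -1)
        dense = dense.reshape(n, self.n_channels, k, k)
        self._dense_cache = (self.weights, dense)
        return dense

    def drive_field(self, field_2d: np.ndarray, valid: bool = False, channel: int = 0) -> np.ndarray:
        """Drive over a whole source sheet without materialising patches.

        Contracts each unit's dense kernel with its (strided, copy-free)
        window of the source field.  Bit-identical to
        ``drive(extract_patches(...))`` is *not* guaranteed (summation order
        differs), so learning-rule code keeps using explicit patches; this
        path serves the settling loop.
        """
        h, k = self.half_width, 2 * self.half_width + 1
        src = field_2d if valid else np.pad(field_2d, h)
        win = sliding_window_view(src, (k, k))
        n0, n1 = win.shape[:2]
        dense = self._dense()[:, channel].reshape(n0, n1, k, k)
        return np.einsum("rcij,rcij->rc", dense, win).ravel()

    def mass_beyond(self, radius_px: float) -> float:
        """Mean kernel mass at lags greater than ``radius_px``.

        Used to monitor pruning of lateral excitation outside the
        astrocytic radius.
        """
        h = self.half_width
        ax = np.arange(-h, h + 1, dtype=float)
        yy, xx = np.meshgrid(ax, ax, indexing="ij")
        far = (np.hypot(yy, xx)[self.mask] > radius_px)
        far = np.tile(far, self.n_channels)
        return float(self.weights[:, far].sum(axis=1).mean())

    def kernel_image(self, unit: int) -> np.ndarray:
        """Dense (n_channels, k, k) view of one unit's kernel, for inspection."""
        k = 2 * self.half_width + 1
        out = np.zeros((self.n_channels, k * k))
        out[:, self.mask_flat] = self.weights[unit].reshape(self.n_channels, -1)
        return out.reshape(self.n_channels, k, k)


def init_projection(
    kind: str,
    radius: float,
    geometry: SheetGeometry,
    rng: np.random.Generator,
    n_channels: int = 1,
    sigma_frac: float = 0.5,
    noise: float = 0.1,
    e_max_scale: float | None = None,
) -> ProjectionField:
    """Initialise a projection as a normalised Gaussian plus uniform noise.

    The Gaussian profile has sigma ``sigma_frac * radius``; independent
    uniform noise of relative amplitude ``noise`` is added per unit (this is
    what seeds the symmetry breaking for orientation selectivity).  Every
    kernel is normalised to unit sum.  With ``noise=0`` the kernel is exactly
    the discrete Gaussian profile.
    """
    radius_px = geometry.to_pixels(radius)
    h = int(np.floor(radius_px))
    if 2 * h + 1 > geometry.n * 2:
        raise ValueError(
            f"projection radius {radius} sheet units exceeds the sheet extent"
        )
    mask = circular_mask(radius_px, h)
    m = int(mask.sum())
    ax = np.arange(-h, h + 1, dtype=float)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    sigma_px = max(sigma_frac * radius_px, 0.5)
    profile = np.exp(-(xx**2 + yy**2) / (2.0 * sigma_px**2))[mask]
    profile = profile / profile.sum()

    n_units = geometry.n * geometry.n
    base = np.tile(profile, n_channels)[None, :] / n_channels
    if noise > 0:
        u = rng.uniform(0.0, 1.0, size=(n_units, n_channels * m))
        w = (1.0 - noise) * base + noise * u / u.sum(axis=1, keepdims=True)
    else:
        w = np.repeat(base, n_units, axis=0)
    w = w / w.sum(axis=1, keepdims=True)

    e_max = np.inf
    normalized = kind != EXCITATORY
    if kind == EXCITATORY and e_max_scale is not None:
        e_max = e_max_scale / m
    return ProjectionField(
        kind=kind,
        radius=radius,
        half_width=h,
        mask=mask,
        weights=w,
        n_channels=n_channels,
        normalized=normalized,
        e_max=e_max,
    )


def hebbian_update(
    weights: np.ndarray, y_post: np.ndarray, pre_patches: np.ndarray, eta: float
) -> np.ndarray:
    """Divisively normalised Hebbian step.

    ``w' = (w + eta * y_post * P) / sum(w + eta * y_post * P)`` per unit.
    Units whose denominator would vanish (all-zero weights and activity)
    keep their previous kernel.
    """
    if eta == 0:
        return weights
    new = weights + eta * y_post[:, None] * pre_patches
    denom = new.sum(axis=1)
    ok = denom > 0
    out = np.where(ok[:, None], new / np.where(ok, denom, 1.0)[:, None], weights)
    return out


def bcm_update(
    weights: np.ndarray,
    y_post: np.ndarray,
    theta: np.ndarray,
    pre_patches: np.ndarray,
    eta: float,
    e_max: float,
    renormalize: bool = True,
) -> np.ndarray:
    """Astrocyte-thresholded BCM step with pruning.

    ``dE = eta * y * (y - theta) * y_pre``; the result is clipped to
    ``[0, e_max]`` — depression below zero prunes the synapse.  With
    ``renormalize`` (default) each unit's kernel is then rescaled to unit
    sum, so the BCM rule shapes the lag profile of lateral excitation while
    its total strength stays bounded; without it the sliding threshold and
    the clip alone limit growth.  Units whose kernel would vanish keep the
    previous weights.
    """
    gain = eta * y_post * (y_post - theta)
    new = np.clip(weights + gain[:, None] * pre_patches, 0.0, e_max)
    if renormalize:
        denom = new.sum(axis=1)
        ok = denom > 0
        new = np.where(ok[:, None], new / np.where(ok, denom, 1.0)[:, None], weights)
    return new
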