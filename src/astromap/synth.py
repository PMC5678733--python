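"""Synthetic orientation maps with known structure.

These generators provide ground-truth fixtures for the analysis suite:
single pinwheels with known charge, sine-grid maps with an exact pinwheel
census, band-pass noise maps with a planted dominant wavelength (a standard
statistical model of orientation preference maps), and idealised cosine
tuning responses for difference-map checks.
"""

from __future__ import annotations

import numpy as np

from .probe import OrientationMap


def _map_from_z(z: np.ndarray, normalize: bool = True) -> OrientationMap:
    sel = np.abs(z)
    if normalize and sel.max() > 0:
        sel = sel / sel.max()
    pref = (np.angle(z) / 2.0) % np.pi
    return OrientationMap(preference=pref, selectivity=sel)


def single_pinwheel(n: int = 64, charge: int = 1) -> OrientationMap:
    """A canonical single pinwheel centred on the grid.

    ``z = (x + iy) / |x + iy|`` for charge +1 (the conjugate for -1); the
    centre falls at pixel ``((n-1)/2, (n-1)/2)``.
    """
    if charge not in (1, -1):
        raise ValueError("charge must be +1 or -1")
    ax = np.arange(n) - (n - 1) / 2.0
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    z = xx + 1j * yy
    if charge == -1:
        z = np.conj(z)
    mag = np.abs(z)
    mag[mag == 0] = 1.0
    return _map_from_z(z / mag, normalize=False)


def sine_grid_map(n: int = 64, periods_x: int = 2, periods_y: int = 1) -> OrientationMap:
    """Doubly periodic map with an exactly known pinwheel census.

    ``z = sin(2 pi periods_x (x - x0) / n) + i sin(2 pi periods_y (y - y0) / n)``
    with quarter-period offsets ``x0, y0`` has zeros wherever both sines
    vanish, all strictly interior to the grid: ``2 periods_x * 2 periods_y``
    pinwheels with alternating charges and zero net charge.
    """
    ax = np.arange(n)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    x0 = n / (4.0 * periods_x) + 0.37
    y0 = n / (4.0 * periods_y) + 0.37
    z = np.sin(2 * np.pi * periods_x * (xx - x0) / n) + 1j * np.sin(
        2 * np.pi * periods_y * (yy - y0) / n
    )
    return _map_from_z(z)


def sine_grid_pinwheel_census(
    n: int, periods_x: int, periods_y: int
) -> tuple[np.ndarray, np.ndarray]:
    """Exact pinwheel centres and charges of :func:`sine_grid_map`.

    Zeros sit at ``x = x0 + j * n / (2 periods_x)``,
    ``y = y0 + i * n / (2 periods_y)`` with the generator's quarter-period-plus-0.37 offsets (chosen so no zero
    falls exactly on a lattice node); the charge alternates as ``(-1)^(i + j)`` on the
    checkerboard of crossings.
    """
    x0 = n / (4.0 * periods_x) + 0.37
    y0 = n / (4.0 * periods_y) + 0.37
    xs = [x0 + j * n / (2.0 * periods_x) for j in range(2 * periods_x)]
    ys = [y0 + i * n / (2.0 * periods_y) for i in range(2 * periods_y)]
    centers, charges = [], []
    for i, y in enumerate(ys):
        for j, x in enumerate(xs):
            centers.append((y, x))
            charges.append(1 if (i + j) % 2 == 0 else -1)
    return np.array(centers), np.array(charges, dtype=int)


def bandpass_noise_map(
    n: int = 64,
    wavelength_px: float = 12.0,
    bandwidth: float = 0.15,
    rng: np.random.Generator | None = None,
) -> OrientationMap:
    """Band-pass filtered complex Gaussian noise with a planted wavelength.

    Complex white noise is filtered with a Gaussian annulus centred on
    ``k0 = n / wavelength_px`` cycles per extent (relative width
    ``bandwidth``); the result is a realistic quasi-periodic orientation
    map whose dominant spectral peak sits at the planted frequency and
    whose pinwheel density is close to pi per squared wavelength.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    noise = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
    freq = np.fft.fftfreq(n, d=1.0 / n)
    kmag = np.hypot(*np.meshgrid(freq, freq, indexing="ij"))
    k0 = n / wavelength_px
    annulus = np.exp(-((kmag - k0) ** 2) / (2.0 * (bandwidth * k0) ** 2))
    z = np.fft.ifft2(np.fft.fft2(noise) * annulus)
    return _map_from_z(z)


def uniform_random_map(
    n: int, rng: np.random.Generator | None = None
) -> OrientationMap:
    """Independent uniform-random preferences (salt-and-pepper extreme)."""
    rng = np.random.default_rng(0) if rng is None else rng
    pref = rng.uniform(0.0, np.pi, size=(n, n))
    return OrientationMap(preference=pref, selectivity=np.ones((n, n)))


def cosine_tuning_responses(
    preference: np.ndarray,
    orientations: np.ndarray,
    selectivity: np.ndarray | None = None,
    baseline: float = 1.0,
) -> np.ndarray:
    """Idealised responses ``r_k = baseline + sel * cos(2 (phi_k - pref))``.

    Stacks one response field per probe orientation; useful as a noiseless
    tuning model when testing difference maps and vector-sum preferences.
    """
    sel = np.ones_like(preference) if selectivity is None else selectivity
    out = np.empty((len(orientations),) + preference.shape)
    for k, phi in enumerate(orientations):
        out[k] = baseline + sel * np.cos(2.0 * (phi - preference))
    return out
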