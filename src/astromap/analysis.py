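"""Quantitative analysis of orientation maps.

Implements the standard column-spacing and pinwheel statistics: cardinal and
oblique difference maps, Fermi high-pass filtering, radially averaged power
spectra with a Gaussian-plus-quadratic peak fit (hypercolumn width), pinwheel
identification from zero-contour crossings of the polar map with topological
charges, the stability index between two maps, and local orientation
similarity curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from skimage import measure

from .probe import OrientationMap

# ---------------------------------------------------------------------------
# difference maps and Fermi filtering
# ---------------------------------------------------------------------------


def difference_maps(omap: OrientationMap) -> dict[str, np.ndarray]:
    """Cardinal and oblique difference maps from stored probe responses.

    ``I'_0_90 = r(0) - r(90deg)`` and ``I'_45_135 = r(45deg) - r(135deg)``.
    Requires the map to carry responses at those four orientations.
    """
    pairs = {"0_90": (0.0, np.pi / 2), "45_135": (np.pi / 4, 3 * np.pi / 4)}
    out = {}
    for name, (a, b) in pairs.items():
        out[name] = omap.response_at(a) - omap.response_at(b)
    return out


def fermi_function(k: np.ndarray, k_hp: float, beta_hp: float) -> np.ndarray:
    """High-pass Fermi transfer ``S(k) = 1 / (1 + exp((k_hp - |k|)/beta))``.

    Equals 1/2 at ``|k| = k_hp`` and tends to a step as ``beta_hp -> 0``.
    """
    return 1.0 / (1.0 + np.exp(np.clip((k_hp - np.abs(k)) / beta_hp, -500, 500)))


@dataclass
class FilteredDifferenceMap:
    """A difference map, its smooth component and the high-passed residual."""

    raw: np.ndarray  # I'
    filtered: np.ndarray  # I = I' - J
    smooth: np.ndarray  # J
    k_hp: float
    beta_hp: float
    W: np.ndarray  # normalisation field (ones on unmasked rectangular maps)


def fermi_highpass(
    i_prime: np.ndarray,
    k_hp: float,
    beta_hp: float,
    convention: str = "highpass",
) -> FilteredDifferenceMap:
    """Remove slow spatial trends from a difference map with a Fermi filter.

    The filtered map is ``I = I' - J`` with ``J`` a smoothed version of
    ``I'``.  Under the default ``highpass`` convention ``J`` keeps the
    frequencies *below* the cutoff, so the composite attenuation of a pure
    spatial frequency ``k`` is exactly the Fermi function ``S(k)`` above.
    The ``printed`` convention instead forms ``J`` with ``S(k)`` itself
    (making the composite a low-pass); it is exposed for comparison only.
    Frequencies are in cycles per map extent; on full rectangular maps the
    ROI normalisation field ``W`` is identically 1.
    """
    if k_hp <= 0:
        raise ValueError("k_hp must be positive")
    if beta_hp <= 0:
        raise ValueError("beta_hp must be positive")
    if convention not in ("highpass", "printed"):
        raise ValueError(f"unknown Fermi convention {convention!r}")
    n0, n1 = i_prime.shape
    ky = np.fft.fftfreq(n0, d=1.0 / n0)
    kx = np.fft.fftfreq(n1, d=1.0 / n1)
    kmag = np.hypot(*np.meshgrid(ky, kx, indexing="ij"))
    s_hp = fermi_function(kmag, k_hp, beta_hp)
    spectrum = np.fft.fft2(i_prime)
    smooth_gain = s_hp if convention == "printed" else (1.0 - s_hp)
    W = np.ones_like(i_prime)
    smooth = np.real(np.fft.ifft2(smooth_gain * spectrum)) / W
    filtered = i_prime - smooth
    return FilteredDifferenceMap(
        raw=i_prime, filtered=filtered, smooth=smooth, k_hp=k_hp, beta_hp=beta_hp, W=W
    )


# ---------------------------------------------------------------------------
# power spectrum and peak fit
# ---------------------------------------------------------------------------


def radial_power_spectrum(
    i_filtered: np.ndarray, pad_to: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Radially averaged power spectrum of a (filtered) difference map.

    The map is zero-padded to a square power-of-two size, transformed, and
    ``P(k) = mean over angle of |I(k)|^2`` is accumulated in rings one
    padded-grid frequency step wide.  The returned ``k`` grid is converted
    to cycles per original map extent.
    """
    n = max(i_filtered.shape)
    if pad_to is None:
        pad_to = 1 << int(np.ceil(np.log2(max(n, 64))))
    if pad_to < n:
        raise ValueError("pad_to smaller than the map")
    padded = np.zeros((pad_to, pad_to))
    padded[: i_filtered.shape[0], : i_filtered.shape[1]] = i_filtered
    power = np.abs(np.fft.fft2(padded)) ** 2
    freq = np.fft.fftfreq(pad_to, d=1.0 / pad_to)
    kmag = np.hypot(*np.meshgrid(freq, freq, indexing="ij"))
    rings = np.rint(kmag).astype(int)
    n_bins = rings.max() + 1
    sums = np.bincount(rings.ravel(), weights=power.ravel(), minlength=n_bins)
    counts = np.bincount(rings.ravel(), minlength=n_bins)
    radial = sums / np.maximum(counts, 1)
    k = np.arange(n_bins) * (n / pad_to)  # cycles per original map extent
    return k, radial


def _peak_model(k, a0, a1, a2, a3, a4, a5):
    return a0 * np.exp(-((k - a1) ** 2) / (2.0 * a2**2)) + a3 + a4 * k + a5 * k**2


@dataclass
class SpectrumFit:
    """Gaussian-plus-quadratic fit of a radial power spectrum peak."""

    k: np.ndarray
    power: np.ndarray
    params: np.ndarray  # a0..a5
    zeta: float  # peak position, cycles per map extent
    residual: float
    converged: bool
    hypercolumn_mm: float = field(default=np.nan)

    @property
    def model(self) -> np.ndarray:
        return _peak_model(self.k, *self.params)


def fit_spectrum_peak(
    k: np.ndarray,
    power: np.ndarray,
    extent_mm: float | None = None,
    exclude_dc: bool = True,
) -> SpectrumFit:
    """Fit ``a0 exp(-(k-a1)^2 / (2 a2^2)) + a3 + a4 k + a5 k^2`` to ``P(k)``.

    The peak position estimate is ``zeta = a1``.  The fit is initialised
    from the raw argmax (the model is multimodal); if the nonlinear fit does
    not converge the raw argmax is returned with ``converged=False``.  With
    ``extent_mm`` given, the hypercolumn width ``Lambda = extent_mm / zeta``
    is filled in.
    """
    k = np.asarray(k, dtype=float)
    power = np.asarray(power, dtype=float)
    sel = slice(1, None) if exclude_dc else slice(None)
    ks, ps = k[sel], power[sel]
    if ks.size < 8:
        raise ValueError("need at least 8 radial bins to fit the peak")
    i0 = int(np.argmax(ps))
    bin_w = float(np.median(np.diff(ks)))
    p0 = [ps[i0], ks[i0], 2.0 * bin_w, float(np.median(ps)), 0.0, 0.0]
    lower = [0.0, ks[0], bin_w / 4.0, -np.inf, -np.inf, -np.inf]
    upper = [np.inf, ks[-1], (ks[-1] - ks[0]), np.inf, np.inf, np.inf]
    try:
        params, _ = curve_fit(
            _peak_model, ks, ps, p0=p0, bounds=(lower, upper), maxfev=20000
        )
        zeta = float(params[1])
        residual = float(np.sqrt(np.mean((_peak_model(ks, *params) - ps) ** 2)))
        converged = True
    except (RuntimeError, ValueError):
        params = np.array(p0)
        zeta = float(ks[i0])
        residual = float("nan")
        converged = False
    lam = extent_mm / zeta if extent_mm is not None and zeta > 0 else np.nan
    return SpectrumFit(
        k=k, power=power, params=np.asarray(params), zeta=zeta,
        residual=residual, converged=converged, hypercolumn_mm=lam,
    )


# ---------------------------------------------------------------------------
# pinwheels
# ---------------------------------------------------------------------------


@dataclass
class PinwheelSet:
    """Detected pinwheel centres with topological charges (+/-1)."""

    centers: np.ndarray  # (m, 2) subpixel (row, col)
    charges: np.ndarray  # (m,) ints in {+1, -1}

    @property
    def count(self) -> int:
        return len(self.charges)

    @property
    def net_charge(self) -> int:
        return int(self.charges.sum()) if self.count else 0


def _segments(contours: list[np.ndarray]) -> np.ndarray:
    segs = [np.stack([c[:-1], c[1:]], axis=1) for c in contours if len(c) > 1]
    if not segs:
        return np.empty((0, 2, 2))
    return np.concatenate(segs, axis=0)


def _segment_intersections(segs_a: np.ndarray, segs_b: np.ndarray) -> list[np.ndarray]:
    """Intersection points between two families of polyline segments."""
    # spatial hash of b-segments by integer cell for near-linear pairing
    cells: dict[tuple[int, int], list[int]] = {}
    for j, s in enumerate(segs_b):
        lo = np.floor(s.min(axis=0)).astype(int)
        hi = np.floor(s.max(axis=0)).astype(int)
        for r in range(lo[0], hi[0] + 1):
            for c in range(lo[1], hi[1] + 1):
                cells.setdefault((r, c), []).append(j)
    points = []
    for s in segs_a:
        lo = np.floor(s.min(axis=0)).astype(int)
        hi = np.floor(s.max(axis=0)).astype(int)
        cand: set[int] = set()
        for r in range(lo[0], hi[0] + 1):
            for c in range(lo[1], hi[1] + 1):
                cand.update(cells.get((r, c), ()))
        p, d1 = s[0], s[1] - s[0]
        for j in cand:
            q, d2 = segs_b[j][0], segs_b[j][1] - segs_b[j][0]
            denom = d1[0] * d2[1] - d1[1] * d2[0]
            if abs(denom) < 1e-14:
                continue
            dq = q - p
            t = (dq[0] * d2[1] - dq[1] * d2[0]) / denom
            u = (dq[0] * d1[1] - dq[1] * d1[0]) / denom
            if -1e-9 <= t <= 1 + 1e-9 and -1e-9 <= u <= 1 + 1e-9:
                points.append(p + t * d1)
    return points


def _plaquette_windings(preference: np.ndarray) -> np.ndarray:
    """Winding number of the doubled angle around every 2x2 grid plaquette.

    The plaquette circuit is the smallest closed circuit around a candidate
    centre, so a pinwheel and its nearby anti-pinwheel partner in an
    adjacent plaquette each keep their own charge.
    """
    two_theta = 2.0 * preference
    a = two_theta[:-1, :-1]
    b = two_theta[:-1, 1:]
    c = two_theta[1:, 1:]
    d = two_theta[1:, :-1]

    def wrap(x: np.ndarray) -> np.ndarray:
        return (x + np.pi) % (2.0 * np.pi) - np.pi

    # counter-clockwise in (x, y) = (col, row) coordinates
    w = wrap(b - a) + wrap(c - b) + wrap(d - c) + wrap(a - d)
    return np.rint(w / (2.0 * np.pi)).astype(int)


def find_pinwheels(omap: OrientationMap, merge_radius: float = 1.0) -> PinwheelSet:
    """Locate pinwheels as crossings of the polar map's zero contours.

    Forms ``z = selectivity * exp(2i * preference)`` and intersects the
    zero-level contours of its real and imaginary parts; intersection points
    are grouped by the grid plaquette that contains them (duplicates from
    adjacent contour segments collapse onto the same cell) and each occupied
    plaquette contributes one centre whose topological charge is the winding
    of the doubled angle around that plaquette.  Cells with zero winding
    (contour tangencies, unresolved dipoles) are discarded.
    """
    if not np.any(omap.selectivity):
        return PinwheelSet(np.empty((0, 2)), np.empty(0, dtype=int))
    z = omap.selectivity * np.exp(2j * omap.preference)
    re, im = z.real, z.imag
    segs_re = _segments(measure.find_contours(re, 0.0))
    segs_im = _segments(measure.find_contours(im, 0.0))
    points = _segment_intersections(segs_re, segs_im)
    if not points:
        return PinwheelSet(np.empty((0, 2)), np.empty(0, dtype=int))

    windings = _plaquette_windings(omap.preference)
    n0, n1 = windings.shape
    cells: dict[tuple[int, int], list[np.ndarray]] = {}
    for pt in sorted(points, key=tuple):
        cell = (int(np.clip(np.floor(pt[0]), 0, n0 - 1)),
                int(np.clip(np.floor(pt[1]), 0, n1 - 1)))
        cells.setdefault(cell, []).append(pt)

    centers, charges = [], []
    for cell, pts in sorted(cells.items()):
        q = int(windings[cell])
        if q == 0:
            continue
        centers.append(np.mean(pts, axis=0))
        charges.append(int(np.sign(q)))
    if not centers:
        return PinwheelSet(np.empty((0, 2)), np.empty(0, dtype=int))
    return PinwheelSet(np.array(centers), np.array(charges, dtype=int))


def pinwheels_per_hypercolumn(
    count: int, hypercolumn_mm: float, extent_mm: float
) -> float:
    """Pinwheel density per hypercolumn area: ``count / (extent^2 / Lambda^2)``."""
    if not np.isfinite(hypercolumn_mm) or hypercolumn_mm <= 0:
        raise ValueError("hypercolumn width is not estimable")
    return count / (extent_mm**2 / hypercolumn_mm**2)


# ---------------------------------------------------------------------------
# stability index and local similarity
# ---------------------------------------------------------------------------


def stability_index(F: np.ndarray, O: np.ndarray) -> float:
    """Stability index between two orientation preference maps.

    ``SI = 1 - (4 / (n pi)) * sum_i |(F_i - O_i) mod (pi/2)|`` over the n
    pixels; 1.0 means identical maps, 0.0 the level of independent random
    maps.
    """
    F = np.asarray(F, dtype=float)
    O = np.asarray(O, dtype=float)
    if F.shape != O.shape:
        raise ValueError(f"shape mismatch {F.shape} vs {O.shape}")
    folded = np.mod(F - O, np.pi / 2.0)
    return float(1.0 - (4.0 / (F.size * np.pi)) * np.abs(folded).sum())


def _disc_offsets(radius_px: float) -> list[tuple[int, int]]:
    h = int(np.floor(radius_px))
    out = []
    for dy in range(-h, h + 1):
        for dx in range(-h, h + 1):
            if dy == dx == 0:
                continue
            if dx * dx + dy * dy <= radius_px**2 + 1e-9:
                out.append((dy, dx))
    return out


def local_orientation_similarity(preference: np.ndarray, radius_px: float) -> float:
    """Map-wide mean angle of separation (degrees) within a disc radius.

    For each node, the folded orientation distance ``min(d, pi - d)`` to
    every other node within ``radius_px`` is averaged; the map-wide mean is
    returned in degrees (0 for a constant map, 45 expected for an
    independent uniform-random map).
    """
    if radius_px < 1.0:
        raise ValueError("radius must be at least one node spacing")
    offsets = _disc_offsets(radius_px)
    n0, n1 = preference.shape
    total = np.zeros_like(preference)
    count = np.zeros_like(preference)
    for dy, dx in offsets:
        src = preference[
            max(0, -dy) : n0 - max(0, dy), max(0, -dx) : n1 - max(0, dx)
        ]
        dst = preference[
            max(0, dy) : n0 - max(0, -dy), max(0, dx) : n1 - max(0, -dx)
        ]
        d = np.abs(src - dst)
        folded = np.minimum(d, np.pi - d)
        total[max(0, -dy) : n0 - max(0, dy), max(0, -dx) : n1 - max(0, dx)] += folded
        count[max(0, -dy) : n0 - max(0, dy), max(0, -dx) : n1 - max(0, dx)] += 1
    ok = count > 0
    per_node = total[ok] / count[ok]
    return float(np.degrees(per_node.mean()))


@dataclass
class SimilarityCurve:
    """Mean local angle of separation as a function of disc radius."""

    radii_mm: np.ndarray
    mean_angle_deg: np.ndarray


def similarity_curve(
    preference: np.ndarray, radii_mm: np.ndarray, mm_per_px: float
) -> SimilarityCurve:
    """Evaluate the local-similarity statistic over a grid of radii (mm).

    Radii below one node spacing are evaluated at one node spacing (the
    smallest representable neighbourhood).
    """
    vals = [
        local_orientation_similarity(preference, max(r / mm_per_px, 1.0))
        for r in radii_mm
    ]
    return SimilarityCurve(np.asarray(radii_mm, float), np.asarray(vals))


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------


@dataclass
class MapAnalysis:
    """Summary statistics of one orientation map."""

    zeta: float
    hypercolumn_mm: float
    n_pinwheels: int
    pw_per_hypercolumn: float
    mean_local_angle_deg: float
    spectrum_fit: SpectrumFit
    pinwheels: PinwheelSet
    k_hp: float
    beta_hp: float
    zeta_sensitive: bool


def analyze_map(
    omap: OrientationMap,
    extent_mm: float,
    k_hp: float | None = None,
    beta_hp: float | None = None,
    similarity_radius_mm: float = 0.25,
) -> MapAnalysis:
    """Run the full column-spacing / pinwheel analysis on one map.

    The two difference maps are Fermi high-passed, their radial power
    spectra averaged, and the spectral peak fitted to give the dominant
    frequency ``zeta`` and hypercolumn width ``Lambda = extent_mm / zeta``.
    The cutoff ``k_hp`` defaults to half the raw spectral argmax (with
    steepness ``k_hp / 8``); the fit is repeated with a doubled cutoff and
    flagged ``zeta_sensitive`` when the peak moves by more than two bins.
    """
    diffs = difference_maps(omap)
    raw_maps = [v - v.mean() for v in diffs.values()]

    # raw spectrum (unfiltered) to anchor the cutoff
    raw_spectra = [radial_power_spectrum(m) for m in raw_maps]
    k = raw_spectra[0][0]
    p_raw = np.mean([p for _, p in raw_spectra], axis=0)
    zeta_raw = float(k[1:][np.argmax(p_raw[1:])])
    if k_hp is None:
        k_hp = max(zeta_raw / 2.0, float(k[1]))
    if beta_hp is None:
        beta_hp = k_hp / 8.0

    def _fit(cutoff: float) -> SpectrumFit:
        spectra = []
        for m in raw_maps:
            filt = fermi_highpass(m, cutoff, beta_hp).filtered
            spectra.append(radial_power_spectrum(filt)[1])
        return fit_spectrum_peak(k, np.mean(spectra, axis=0), extent_mm=extent_mm)

    fit = _fit(k_hp)
    fit2 = _fit(2.0 * k_hp)
    bin_w = float(k[1] - k[0])
    zeta_sensitive = abs(fit.zeta - fit2.zeta) > 2.0 * bin_w

    pw = find_pinwheels(omap)
    density = pinwheels_per_hypercolumn(pw.count, fit.hypercolumn_mm, extent_mm)
    mm_per_px = extent_mm / omap.shape[0]
    local = local_orientation_similarity(
        omap.preference, max(similarity_radius_mm / mm_per_px, 1.0)
    )
    return MapAnalysis(
        zeta=fit.zeta,
        hypercolumn_mm=fit.hypercolumn_mm,
        n_pinwheels=pw.count,
        pw_per_hypercolumn=density,
        mean_local_angle_deg=local,
        spectrum_fit=fit,
        pinwheels=pw,
        k_hp=k_hp,
        beta_hp=beta_hp,
        zeta_sensitive=zeta_sensitive,
    )
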