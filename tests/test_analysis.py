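import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from astromap import (
    OrientationMap,
    difference_maps,
    fermi_function,
    fermi_highpass,
    find_pinwheels,
    fit_spectrum_peak,
    local_orientation_similarity,
    pinwheels_per_hypercolumn,
    radial_power_spectrum,
    stability_index,
)
from astromap.analysis import _peak_model
from astromap.synth import (
    bandpass_noise_map,
    cosine_tuning_responses,
    sine_grid_map,
    sine_grid_pinwheel_census,
    single_pinwheel,
    uniform_random_map,
)


def plaquette_winding_oracle(preference):
    """Independent pinwheel census: winding of the doubled angle around
    every 2x2 plaquette of the preference map."""
    two_theta = 2.0 * preference
    a = two_theta[:-1, :-1]
    b = two_theta[:-1, 1:]
    c = two_theta[1:, 1:]
    d = two_theta[1:, :-1]

    def wrap(x):
        return (x + np.pi) % (2 * np.pi) - np.pi

    w = wrap(b - a) + wrap(c - b) + wrap(d - c) + wrap(a - d)
    charges = np.rint(w / (2 * np.pi)).astype(int)
    rows, cols = np.nonzero(charges)
    return list(zip(rows, cols)), charges[rows, cols]


# -- difference maps --------------------------------------------------------


def _map_with_responses(pref, sel=None):
    angles = np.arange(8) * np.pi / 8
    responses = cosine_tuning_responses(pref, angles, selectivity=sel)
    p, s = pref, np.ones_like(pref) if sel is None else sel
    return OrientationMap(p, s, orientations=angles, responses=responses)


def test_difference_maps_identical_responses_vanish():
    omap = _map_with_responses(np.full((8, 8), 0.0))
    omap.responses[:] = 1.0
    d = difference_maps(omap)
    assert not np.any(d["0_90"]) and not np.any(d["45_135"])


def test_difference_map_antisymmetry_and_sign():
    pref = np.zeros((8, 8))  # every node prefers 0 degrees
    d = difference_maps(_map_with_responses(pref))
    assert np.all(d["0_90"] > 0)
    np.testing.assert_allclose(d["45_135"], 0.0, atol=1e-12)


def test_difference_maps_require_responses():
    omap = OrientationMap(np.zeros((4, 4)), np.ones((4, 4)))
    with pytest.raises(ValueError):
        difference_maps(omap)


# -- Fermi filter -----------------------------------------------------------


def test_fermi_midpoint_is_half():
    assert fermi_function(np.array([5.0]), k_hp=5.0, beta_hp=0.7)[0] == pytest.approx(0.5)


def test_fermi_step_limit():
    beta = 1e-3
    k_hp = 4.0
    below = fermi_function(np.array([k_hp - 10 * beta]), k_hp, beta)[0]
    above = fermi_function(np.array([k_hp + 10 * beta]), k_hp, beta)[0]
    assert below < 1e-4 and above > 1 - 1e-4


def test_fermi_filter_attenuation_matches_transfer_function():
    """Attenuation of pure on-grid sinusoids equals S(k) to high precision."""
    n = 64
    k_hp, beta = 6.0, 0.75
    x = np.arange(n)
    yy, xx = np.meshgrid(x, x, indexing="ij")
    for kx, ky in [(2, 0), (4, 3), (8, 0), (6, 6), (12, 5)]:
        wave = np.cos(2 * np.pi * (kx * xx + ky * yy) / n)
        out = fermi_highpass(wave, k_hp, beta).filtered
        gain = np.linalg.norm(out) / np.linalg.norm(wave)
        expected = fermi_function(np.array([np.hypot(kx, ky)]), k_hp, beta)[0]
        assert abs(gain - expected) < 1e-6


def test_fermi_printed_convention_is_complementary():
    n = 32
    rng = np.random.default_rng(0)
    field = rng.normal(size=(n, n))
    hp = fermi_highpass(field, 4.0, 0.5, convention="highpass")
    lp = fermi_highpass(field, 4.0, 0.5, convention="printed")
    # the two conventions split the field into complementary bands
    np.testing.assert_allclose(hp.filtered + lp.filtered, field, atol=1e-9)
    np.testing.assert_allclose(hp.smooth, lp.filtered, atol=1e-9)


def test_fermi_validates_parameters():
    field = np.zeros((8, 8))
    with pytest.raises(ValueError):
        fermi_highpass(field, -1.0, 0.5)
    with pytest.raises(ValueError):
        fermi_highpass(field, 2.0, 0.0)


# -- power spectrum ---------------------------------------------------------


def test_radial_spectrum_peaks_at_planted_frequency():
    n = 48
    k0 = 6
    x = np.arange(n)
    wave = np.cos(2 * np.pi * k0 * x / n)[None, :] * np.ones((n, 1))
    k, p = radial_power_spectrum(wave, pad_to=n)
    assert k[np.argmax(p[1:]) + 1] == pytest.approx(k0)


def test_radial_spectrum_parseval():
    rng = np.random.default_rng(2)
    field = rng.normal(size=(32, 32))
    k, p = radial_power_spectrum(field, pad_to=32)
    freq = np.fft.fftfreq(32, d=1 / 32)
    kmag = np.hypot(*np.meshgrid(freq, freq, indexing="ij"))
    rings = np.rint(kmag).astype(int)
    counts = np.bincount(rings.ravel())
    keep = min(len(counts), len(p))
    total = (counts[:keep] * p[:keep]).sum()
    assert total == pytest.approx(np.sum(np.abs(np.fft.fft2(field)) ** 2), rel=1e-6)


def test_radial_spectrum_rotation_invariant():
    rng = np.random.default_rng(3)
    field = rng.normal(size=(40, 40))
    k1, p1 = radial_power_spectrum(field)
    k2, p2 = radial_power_spectrum(np.rot90(field))
    np.testing.assert_allclose(p1, p2, atol=1e-8 * p1.max())


# -- spectrum peak fit ------------------------------------------------------


def test_fit_recovers_exact_gaussian_peak():
    k = np.arange(0, 21, dtype=float)
    p = _peak_model(k, 1.0, 6.0, 1.0, 0.0, 0.0, 0.0)
    fit = fit_spectrum_peak(k, p, extent_mm=3.0)
    assert fit.converged
    assert fit.zeta == pytest.approx(6.0, abs=1e-6)
    assert fit.hypercolumn_mm == pytest.approx(0.5, abs=1e-6)


def test_fit_robust_to_linear_background():
    k = np.arange(0, 21, dtype=float)
    p = _peak_model(k, 1.0, 6.0, 1.0, 0.0, 0.01, 0.0)
    fit = fit_spectrum_peak(k, p)
    assert fit.zeta == pytest.approx(6.0, abs=1e-3)


def test_fit_requires_enough_bins():
    with pytest.raises(ValueError):
        fit_spectrum_peak(np.arange(5.0), np.ones(5))


def test_planted_wavelength_recovered_from_synthetic_maps():
    """Band-pass noise maps with a planted column spacing: the fitted peak
    lands within one radial bin of the planted frequency."""
    n = 64
    for seed in range(6):
        omap = bandpass_noise_map(n=n, wavelength_px=12.0, rng=np.random.default_rng(seed))
        z = omap.selectivity * np.exp(2j * omap.preference)
        field = z.real - z.real.mean()
        k, p = radial_power_spectrum(field, pad_to=n)
        fit = fit_spectrum_peak(k, p)
        assert abs(fit.zeta - n / 12.0) <= 1.0


def test_three_periods_across_3mm_gives_lambda_1mm():
    n = 60
    x = np.arange(n)
    yy, xx = np.meshgrid(x, x, indexing="ij")
    field = np.cos(2 * np.pi * 3 * xx / n) * np.cos(2 * np.pi * 0.5 * yy / n)
    k, p = radial_power_spectrum(field)
    fit = fit_spectrum_peak(k, p, extent_mm=3.0)
    bin_width = k[1] - k[0]
    assert abs(fit.zeta - 3.0) <= bin_width
    assert abs(fit.hypercolumn_mm - 1.0) <= 3.0 / (3.0 - bin_width) - 1.0 + 1e-9


# -- pinwheels --------------------------------------------------------------


def test_single_pinwheel_detected_at_center():
    omap = single_pinwheel(64, charge=1)
    pw = find_pinwheels(omap)
    assert pw.count == 1
    np.testing.assert_allclose(pw.centers[0], [31.5, 31.5], atol=0.5)
    assert pw.charges[0] == 1


def test_conjugate_pinwheel_has_opposite_charge():
    pw = find_pinwheels(single_pinwheel(64, charge=-1))
    assert pw.count == 1
    assert pw.charges[0] == -1


def test_sine_grid_census_matches_winding_oracle():
    omap = sine_grid_map(64, periods_x=2, periods_y=1)
    expected_centers, expected_charges = sine_grid_pinwheel_census(64, 2, 1)
    pw = find_pinwheels(omap)
    oracle_cells, oracle_charges = plaquette_winding_oracle(omap.preference)
    assert pw.count == len(oracle_cells) == len(expected_centers) == 8
    assert pw.net_charge == 0
    # exact bijection: each flagged plaquette contains one detection of the
    # same charge
    det_cells = {tuple(np.floor(c).astype(int)): q for c, q in zip(pw.centers, pw.charges)}
    for cell, q in zip(oracle_cells, oracle_charges):
        assert det_cells[tuple(cell)] == q


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_bandpass_map_detector_equals_oracle(seed):
    omap = bandpass_noise_map(48, wavelength_px=11.0, rng=np.random.default_rng(seed))
    pw = find_pinwheels(omap)
    cells, charges = plaquette_winding_oracle(omap.preference)
    assert pw.count == len(cells)
    det_cells = {tuple(np.floor(c).astype(int)): q for c, q in zip(pw.centers, pw.charges)}
    for cell, q in zip(cells, charges):
        assert det_cells[tuple(cell)] == q


def test_periodic_map_net_charge_zero():
    for seed in range(3):
        omap = bandpass_noise_map(48, wavelength_px=10.0, rng=np.random.default_rng(seed))
        assert find_pinwheels(omap).net_charge == plaquette_winding_oracle(omap.preference)[1].sum()


def test_empty_map_gives_empty_set():
    omap = OrientationMap(np.zeros((8, 8)), np.zeros((8, 8)))
    assert find_pinwheels(omap).count == 0


def test_pinwheel_density_arithmetic():
    assert pinwheels_per_hypercolumn(9, 1.0, 3.0) == pytest.approx(1.0)
    assert pinwheels_per_hypercolumn(9, 2.0, 3.0) == pytest.approx(4.0)
    with pytest.raises(ValueError):
        pinwheels_per_hypercolumn(9, np.nan, 3.0)


# -- stability index --------------------------------------------------------


def test_stability_index_of_identical_maps_is_exactly_one(rng):
    F = rng.uniform(0, np.pi, (32, 32))
    assert stability_index(F, F.copy()) == 1.0


def test_stability_index_quarter_turn_offset_is_zero(rng):
    F = rng.uniform(0, np.pi / 2, (16, 16))
    O = F - np.pi / 4
    assert stability_index(F, O) == pytest.approx(0.0, abs=1e-12)


def test_stability_index_independent_maps_near_zero():
    rng = np.random.default_rng(99)
    vals = [
        stability_index(
            rng.uniform(0, np.pi, (48, 48)), rng.uniform(0, np.pi, (48, 48))
        )
        for _ in range(100)
    ]
    assert np.all(np.abs(vals) < 0.05)
    assert abs(np.mean(vals)) < 0.01


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_stability_index_bounded_and_maximal_iff_equal(seed):
    rng = np.random.default_rng(seed)
    F = rng.uniform(0, np.pi, (8, 8))
    O = rng.uniform(0, np.pi, (8, 8))
    assert stability_index(F, O) <= 1.0
    assert stability_index(F, F) == 1.0


def test_stability_index_shape_mismatch():
    with pytest.raises(ValueError):
        stability_index(np.zeros((4, 4)), np.zeros((5, 5)))


# -- local similarity -------------------------------------------------------


def test_constant_map_has_zero_local_angle():
    assert local_orientation_similarity(np.full((20, 20), 0.7), 3.0) == pytest.approx(0.0)


def test_uniform_random_map_local_angle_near_45():
    omap = uniform_random_map(48, np.random.default_rng(5))
    angle = local_orientation_similarity(omap.preference, 4.0)
    assert abs(angle - 45.0) < 1.0


def test_smooth_map_smoother_than_shuffled():
    rng = np.random.default_rng(7)
    omap = bandpass_noise_map(48, wavelength_px=12.0, rng=rng)
    smooth = local_orientation_similarity(omap.preference, 3.0)
    shuffled = omap.preference.copy().ravel()
    rng.shuffle(shuffled)
    assert smooth < local_orientation_similarity(shuffled.reshape(48, 48), 3.0)


def test_radius_below_spacing_rejected():
    with pytest.raises(ValueError):
        local_orientation_similarity(np.zeros((8, 8)), 0.5)
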