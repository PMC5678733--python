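import numpy as np
import pytest

from astromap import (
    DivergenceError,
    ModelConfig,
    SheetGeometry,
    homeostatic_update,
    init_projection,
    synaptic_drive,
    v1_settle_from_aff,
)
from astromap.projections import EXCITATORY, INHIBITORY


@pytest.fixture
def lateral(rng):
    geom = SheetGeometry(extent=1.0, density=16)
    E = init_projection(EXCITATORY, 0.22, geom, rng, e_max_scale=4.0)
    I = init_projection(INHIBITORY, 0.22, geom, rng)
    return geom, E, I


def test_zero_input_zero_activity(lateral):
    geom, E, I = lateral
    cfg = ModelConfig(density=16)
    y, gs = v1_settle_from_aff(np.zeros(geom.n**2), E, I, np.zeros(geom.n**2), cfg)
    assert not np.any(y)
    assert not np.any(gs)


def test_no_recurrence_settles_in_one_step(lateral, rng):
    """With q = r = 0 the settled rates equal the rectified afferent drive
    and further settling changes nothing."""
    geom, E, I = lateral
    aff = rng.random(geom.n**2)
    rho = np.full(geom.n**2, 0.3)
    one = ModelConfig(density=16, q=0.0, r=0.0, settling_steps=1)
    many = ModelConfig(density=16, q=0.0, r=0.0, settling_steps=9)
    y1, _ = v1_settle_from_aff(aff, E, I, rho, one)
    y9, _ = v1_settle_from_aff(aff, E, I, rho, many)
    np.testing.assert_array_equal(y1, y9)
    np.testing.assert_allclose(
        y1.ravel(), np.minimum(np.maximum(1.5 * aff - rho, 0.0), 1.0), atol=1e-12
    )


def test_settled_activity_is_sparse_blobs(rng):
    """With the standard strengths, a single oriented stimulus activates a
    contiguous minority of the sheet (competition, not ignition)."""
    from astromap.model import AstroGCALModel

    cfg = ModelConfig(density=24, seed=3)
    cfg.homeostasis.rho_init = 0.3
    model = AstroGCALModel(cfg)
    fracs = []
    for _ in range(20):
        res = model.respond(_random_stimulus_field(model, rng), learn=False)
        fracs.append((res.y > 0).mean())
    assert np.mean(fracs) < 0.5
    assert max(fracs) > 0.0


def _random_stimulus_field(model, rng):
    from astromap.stimuli import render_stimulus, sample_training_stimulus

    stim = sample_training_stimulus(rng, model.lgn_geom, model.config.stimuli)
    return render_stimulus(stim, model.retina_geom)


def test_synaptic_drive_variants(lateral, rng):
    geom, E, I = lateral
    cfg = ModelConfig(density=16)
    aff = rng.random(geom.n**2)
    y = rng.random(geom.shape)
    full = synaptic_drive(aff, y, E, I, cfg, variant="full")
    no_gaba = synaptic_drive(aff, y, E, I, cfg, variant="no_gaba")
    assert np.all(no_gaba >= full - 1e-15)
    with pytest.raises(ValueError):
        synaptic_drive(aff, y, E, I, cfg, variant="bogus")
    assert not np.any(synaptic_drive(np.zeros(geom.n**2), np.zeros(geom.shape), E, I, cfg))


def test_settle_final_drive_shares_code_path(lateral, rng):
    """gs returned by settling equals synaptic_drive at the penultimate rates."""
    geom, E, I = lateral
    cfg = ModelConfig(density=16, settling_steps=5)
    aff = rng.random(geom.n**2)
    rho = np.zeros(geom.n**2)
    y, gs = v1_settle_from_aff(aff, E, I, rho, cfg)
    cfg4 = ModelConfig(density=16, settling_steps=4)
    y4, _ = v1_settle_from_aff(aff, E, I, rho, cfg4)
    expected = synaptic_drive(aff, y4, E, I, cfg, variant="full")
    np.testing.assert_array_equal(gs.ravel(), expected)


def test_divergence_reports_strengths(lateral, rng):
    geom, E, I = lateral
    cfg = ModelConfig(density=16, q=50.0, settling_steps=40, y_max=None)
    E.weights = E.weights * np.inf
    with pytest.raises(DivergenceError, match="q=50.0"):
        v1_settle_from_aff(rng.random(geom.n**2), E, I, np.zeros(geom.n**2), cfg)


def test_homeostasis_printed_fixed_point():
    """With lam * mu = mu (lam = 1) and y = ybar = mu, the printed rule
    leaves the threshold unchanged."""
    mu = 0.3
    ybar, rho = homeostatic_update(
        np.array([mu]), np.array([mu]), np.array([0.2]), beta=0.5, lam=1.0, mu=mu,
        form="printed",
    )
    np.testing.assert_allclose(ybar, [mu])
    np.testing.assert_allclose(rho, [0.2])


def test_homeostasis_beta_one_freezes_trace():
    ybar, _ = homeostatic_update(
        np.array([5.0]), np.array([1.0]), np.array([0.0]), beta=1.0, lam=0.1, mu=0.0
    )
    np.testing.assert_allclose(ybar, [1.0])


@pytest.mark.parametrize("form,lam", [("balanced", 0.1), ("printed", 0.5)])
def test_threshold_rises_monotonically_under_high_activity(form, lam):
    """A unit held above its target activity sees its threshold climb."""
    y = np.array([0.8])
    ybar = np.array([0.8])
    rho = np.array([0.0])
    mu = 0.024
    prev = rho.copy()
    for _ in range(100):
        ybar, rho = homeostatic_update(y, ybar, rho, 0.9, lam, mu, form)
        assert rho[0] > prev[0]
        prev = rho.copy()


def test_unknown_homeostasis_form_rejected():
    with pytest.raises(ValueError):
        homeostatic_update(np.zeros(1), np.zeros(1), np.zeros(1), 0.5, 0.1, 0.0, "x")
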