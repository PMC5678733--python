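import numpy as np
import pytest

import astromap.driver as driver_mod
from astromap import ModelConfig, RunSchedule, probe_orientation_map, run_sweep, train
from astromap.model import AstroGCALModel


@pytest.fixture
def fast_config():
    cfg = ModelConfig(density=16, seed=11)
    return cfg


@pytest.fixture
def fast_probe():
    return {"n_orientations": 4, "n_phases": 2}


def test_schedule_filters_probe_iterations():
    s = RunSchedule(total_iterations=100, probe_iterations=(50, 100, 250, 1000))
    assert s.probe_iterations == (50, 100)
    with pytest.raises(ValueError):
        RunSchedule(sweep_radii_mm=(0.1, -0.2))


def test_zero_iterations_probes_initial_weights(fast_config, fast_probe):
    schedule = RunSchedule(total_iterations=0, probe_iterations=())
    result = train(fast_config, schedule, probe_kwargs=fast_probe)
    fresh = probe_orientation_map(AstroGCALModel(fast_config), **fast_probe)
    np.testing.assert_array_equal(result.maps[0]["neuronal"].preference, fresh.preference)


def test_training_is_bitwise_reproducible(fast_config, fast_probe):
    schedule = RunSchedule(total_iterations=8, probe_iterations=(4, 8))
    a = train(fast_config, schedule, probe_kwargs=fast_probe)
    b = train(fast_config, schedule, probe_kwargs=fast_probe)
    assert a.model.state_fingerprint() == b.model.state_fingerprint()
    for it in (4, 8):
        for layer in ("neuronal", "astrocyte"):
            np.testing.assert_array_equal(
                a.maps[it][layer].preference, b.maps[it][layer].preference
            )
            np.testing.assert_array_equal(
                a.maps[it][layer].responses, b.maps[it][layer].responses
            )


def test_probing_does_not_perturb_training(fast_config, fast_probe):
    """A run probed mid-way ends at exactly the same weights as an
    unprobed run of the same length."""
    probed = train(
        fast_config, RunSchedule(total_iterations=6, probe_iterations=(2, 4)),
        probe_kwargs=fast_probe,
    )
    unprobed = train(
        fast_config, RunSchedule(total_iterations=6, probe_iterations=()),
        probe_kwargs=fast_probe,
    )
    assert probed.model.state_fingerprint() == unprobed.model.state_fingerprint()


def test_train_writes_artifacts(tmp_path, fast_config, fast_probe):
    schedule = RunSchedule(total_iterations=2, probe_iterations=(2,))
    train(fast_config, schedule, out_dir=tmp_path, probe_kwargs=fast_probe)
    assert (tmp_path / "checkpoint.h5").exists()
    assert (tmp_path / "config.yaml").exists()
    assert (tmp_path / "map_neuronal_000002.h5").exists()
    assert (tmp_path / "map_astrocyte_000002.h5").exists()


def test_checkpoint_roundtrip(fast_config):
    model = AstroGCALModel(fast_config)
    model.train(4)


def test_checkpoint_save_load_identical(tmp_path, fast_config):
    model = AstroGCALModel(fast_config)
    model.train(3)
    path = tmp_path / "ckpt.h5"
    model.save_checkpoint(path)
    loaded = AstroGCALModel.load_checkpoint(path)
    assert loaded.state_fingerprint() == model.state_fingerprint()
    assert loaded.config.to_dict() == model.config.to_dict()


def test_sweep_single_cell_populates_all_columns(tmp_path, fast_config, fast_probe):
    schedule = RunSchedule(
        total_iterations=10,
        probe_iterations=(10,),
        sweep_radii_mm=(0.1125,),
        seeds=(11,),
    )
    table = run_sweep(fast_config, schedule, out_dir=tmp_path, probe_kwargs=fast_probe)
    assert len(table) == 1
    row = table.iloc[0]
    assert row["radius_mm"] == 0.1125 and row["seed"] == 11
    for col in ("lambda_mm", "pw_per_hc", "si_neuro_astro", "mean_local_angle_deg"):
        assert np.isfinite(row[col]) or row["error"]
    assert (tmp_path / "sweep_summary.csv").exists()


def test_sweep_records_failures_and_continues(monkeypatch, fast_config, fast_probe):
    real_train = driver_mod.train

    def flaky(cfg, schedule, **kw):
        if cfg.astrocyte.radius_mm < 0.05:
            raise RuntimeError("boom")
        return real_train(cfg, schedule, **kw)

    monkeypatch.setattr(driver_mod, "train", flaky)
    schedule = RunSchedule(
        total_iterations=5, probe_iterations=(5,), sweep_radii_mm=(0.015, 0.1125),
        seeds=(1,),
    )
    table = run_sweep(fast_config, schedule, probe_kwargs=fast_probe)
    assert len(table) == 2
    bad = table[table.radius_mm == 0.015].iloc[0]
    good = table[table.radius_mm == 0.1125].iloc[0]
    assert "boom" in bad["error"]
    assert good["error"] == ""


def test_sweep_requires_radii_and_seeds(fast_config):
    with pytest.raises(ValueError):
        run_sweep(fast_config, RunSchedule(sweep_radii_mm=(), seeds=(1,)))
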