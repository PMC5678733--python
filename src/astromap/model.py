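"""The astrocyte-gated GCAL model: sheets, projections, one-presentation step.

Wiring: retina -> ON/OFF LGN (DoG + gain control) -> V1 (afferent, lateral
excitatory, lateral inhibitory projections) -> astrocyte layer (disc pooling
of the synaptic drive).  Per presentation: draw and render a stimulus,
settle the LGN, settle V1 from rest, activate the astrocytes, then apply the
plasticity rules (Hebbian on A and I, astrocyte-thresholded BCM on E) and
the homeostatic threshold update.

Three named, seeded random streams (stimuli, weight init, gap junctions)
make model variants comparable stimulus-by-stimulus and runs bitwise
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .astro import AstrocyteLayer, AstrocyteState
from .config import ModelConfig
from .cortex import (
    afferent_drive,
    homeostatic_update,
    synaptic_drive,
    v1_settle_from_aff,
)
from .geometry import SheetGeometry
from .lgn import LGNStage, LGNState
from .projections import (
    AFFERENT,
    EXCITATORY,
    INHIBITORY,
    ProjectionField,
    bcm_update,
    extract_patches,
    hebbian_update,
    init_projection,
)
from .stimuli import TrainingStimulus, render_stimulus, sample_training_stimulus

_STREAMS = {"stimuli": 1, "weights": 2, "gap": 3}


@dataclass
class PresentationResult:
    """Everything observable about one stimulus presentation."""

    stimulus: TrainingStimulus | None
    retina: np.ndarray
    lgn: LGNState
    y: np.ndarray
    gs: np.ndarray
    astro: AstrocyteState

    def save(self, path: str | Path, seed: int = 0, iteration: int = 0) -> None:
        """Store the stimulus and LGN activities in an HDF5 file.

        Datasets: ``retina``, ``lgn_on``, ``lgn_off``; attributes ``seed``
        and ``iteration``.
        """
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("retina", data=self.retina)
            f.create_dataset("lgn_on", data=self.lgn.on)
            f.create_dataset("lgn_off", data=self.lgn.off)
            f.attrs["seed"] = seed
            f.attrs["iteration"] = iteration


class AstroGCALModel:
    """A complete model instance with mutable weights and state."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        self.cortex_geom = SheetGeometry(config.extent, config.density, config.mm_per_unit)

        rng_w = np.random.default_rng([config.seed, _STREAMS["weights"]])
        self.rng_stimuli = np.random.default_rng([config.seed, _STREAMS["stimuli"]])
        rng_gap = np.random.default_rng([config.seed, _STREAMS["gap"]])

        self.A = init_projection(
            AFFERENT,
            config.rad_A,
            self.cortex_geom,
            rng_w,
            n_channels=2,
            sigma_frac=config.init_sigma_frac_A,
            noise=config.init_noise_A,
        )
        self.E = init_projection(
            EXCITATORY,
            config.rad_I,
            self.cortex_geom,
            rng_w,
            sigma_frac=config.init_sigma_frac_E,
            noise=config.init_noise_lat,
            e_max_scale=config.e_max_scale,
        )
        self.I = init_projection(
            INHIBITORY,
            config.rad_I,
            self.cortex_geom,
            rng_w,
            sigma_frac=config.init_sigma_frac_I,
            noise=config.init_noise_lat,
        )

        # LGN sheet exceeds cortex by the afferent support; retina exceeds the
        # LGN sheet by the DoG support, so every receptive field is complete.
        self.lgn_geom = self.cortex_geom.expanded(self.A.half_width)
        dog_h = int(round(config.lgn.effective_support * config.density))
        self.retina_geom = self.lgn_geom.expanded(dog_h)
        self.lgn_stage = LGNStage(config.lgn, self.retina_geom, self.lgn_geom)

        self.astro_layer = AstrocyteLayer(
            config.astrocyte, self.cortex_geom, rng=rng_gap
        )

        n_units = self.cortex_geom.n**2
        self.rho = np.full(n_units, config.homeostasis.rho_init)
        self.ybar = np.full(n_units, config.homeostasis.mu)
        self.iteration = 0
        self.n_redrawn = 0

    # -- forward pass ------------------------------------------------------

    def respond(self, retina: np.ndarray, learn: bool = False) -> PresentationResult:
        """Settle the full network on a retinal field; optionally learn.

        With ``learn=False`` no weight, threshold or normaliser state is
        touched, so probing never mutates the model.
        """
        cfg = self.config
        lgn = self.lgn_stage.settle(retina)
        aff = afferent_drive(self.A, lgn.on, lgn.off)

        if learn and cfg.learn_per_step:
            return self._respond_learning_per_step(retina, lgn, aff)

        y, gs_full = v1_settle_from_aff(aff, self.E, self.I, self.rho, cfg)
        if cfg.variant == "no_gaba":
            gs = synaptic_drive(aff, y, self.E, self.I, cfg, variant="no_gaba").reshape(
                y.shape
            )
        else:
            gs = gs_full
        astro = self.astro_layer.activate(gs, update_norm=learn)

        if learn:
            on_p = extract_patches(lgn.on, self.A.half_width, self.A.mask_flat, valid=True)
            off_p = extract_patches(lgn.off, self.A.half_width, self.A.mask_flat, valid=True)
            self._apply_plasticity(y, np.concatenate([on_p, off_p], axis=1), astro)
        return PresentationResult(None, retina, lgn, y, gs, astro)

    def _respond_learning_per_step(
        self, retina: np.ndarray, lgn: LGNState, aff: np.ndarray
    ) -> PresentationResult:
        """Settling with weight updates applied after every step.

        The per-presentation protocol (updates once, after settling) is the
        default; this variant applies the same plasticity rules to each
        intermediate rate pattern instead.
        """
        cfg = self.config
        n = self.cortex_geom.n
        on_p = extract_patches(lgn.on, self.A.half_width, self.A.mask_flat, valid=True)
        off_p = extract_patches(lgn.off, self.A.half_width, self.A.mask_flat, valid=True)
        lgn_patches = np.concatenate([on_p, off_p], axis=1)
        y = np.zeros((n, n))
        y_max = np.inf if cfg.y_max is None else cfg.y_max
        gs = cfg.p * aff
        astro = None
        for _ in range(cfg.settling_steps):
            gs = synaptic_drive(aff, y, self.E, self.I, cfg, variant="full")
            y = np.clip(gs - self.rho, 0.0, y_max).reshape(n, n)
            gs_variant = (
                synaptic_drive(aff, y, self.E, self.I, cfg, variant="no_gaba")
                if cfg.variant == "no_gaba"
                else gs
            )
            astro = self.astro_layer.activate(gs_variant.reshape(n, n), update_norm=True)
            self._apply_plasticity(y, lgn_patches, astro)
        return PresentationResult(None, retina, lgn, y, gs.reshape(n, n), astro)

    def _apply_plasticity(
        self, y: np.ndarray, lgn_patches: np.ndarray, astro: AstrocyteState
    ) -> None:
        cfg = self.config
        y_flat = y.ravel()
        y_patches = extract_patches(y, self.E.half_width, self.E.mask_flat, valid=False)
        theta = 1.0 - astro.S.ravel()
        self.A.weights = hebbian_update(self.A.weights, y_flat, lgn_patches, cfg.eta_A)
        self.I.weights = hebbian_update(self.I.weights, y_flat, y_patches, cfg.eta_I)
        self.E.weights = bcm_update(
            self.E.weights, y_flat, theta, y_patches, cfg.eta_E, self.E.e_max,
            renormalize=cfg.e_normalize,
        )
        h = cfg.homeostasis
        self.ybar, self.rho = homeostatic_update(
            y_flat, self.ybar, self.rho, h.beta, h.lam, h.mu, h.form, h.max_step
        )

    def present(self, stimulus: TrainingStimulus | None = None) -> PresentationResult:
        """One training presentation (draws a stimulus if none is given).

        All-zero presentations (stimulus rendered off-sheet) are re-drawn
        and counted in ``n_redrawn``.
        """
        for _ in range(20):
            # centres are drawn over the LGN-visible extent (plus margin), so
            # stimuli may straddle edges but are rarely wholly invisible
            stim = stimulus or sample_training_stimulus(
                self.rng_stimuli, self.lgn_geom, self.config.stimuli
            )
            retina = render_stimulus(stim, self.retina_geom)
            if retina.max() > 1e-12 or stimulus is not None:
                break
            self.n_redrawn += 1
        result = self.respond(retina, learn=True)
        self.iteration += 1
        return PresentationResult(stim, retina, result.lgn, result.y, result.gs, result.astro)

    def train(self, n_iterations: int) -> None:
        """Run ``n_iterations`` training presentations."""
        for _ in range(n_iterations):
            self.present()

    # -- checkpointing -----------------------------------------------------

    def save_checkpoint(self, path: str | Path) -> None:
        """Write weights and state to an HDF5 checkpoint."""
        import h5py
        import yaml

        with h5py.File(path, "w") as f:
            w = f.create_group("weights")
            w.create_dataset("A", data=self.A.weights)
            w.create_dataset("E", data=self.E.weights)
            w.create_dataset("I", data=self.I.weights)
            s = f.create_group("state")
            s.create_dataset("rho", data=self.rho)
            s.create_dataset("ybar", data=self.ybar)
            s.create_dataset(
                "S",
                data=self.astro_layer.activate(
                    np.zeros(self.cortex_geom.shape), update_norm=False
                ).S,
            )
            f.attrs["iteration"] = self.iteration
            f.attrs["seed"] = self.config.seed
            f.attrs["variant"] = self.config.variant
            f.attrs["R_astro_mm"] = self.config.astrocyte.radius_mm
            f.attrs["running_max"] = self.astro_layer.running_max
            f.attrs["config"] = yaml.safe_dump(self.config.to_dict())

    @classmethod
    def load_checkpoint(cls, path: str | Path) -> "AstroGCALModel":
        """Rebuild a model from a checkpoint (weights, thresholds, counters)."""
        import h5py
        import yaml

        with h5py.File(path, "r") as f:
            cfg = ModelConfig.from_dict(yaml.safe_load(f.attrs["config"]))
            model = cls(cfg)
            model.A.weights = f["weights/A"][...]
            model.E.weights = f["weights/E"][...]
            model.I.weights = f["weights/I"][...]
            model.rho = f["state/rho"][...]
            model.ybar = f["state/ybar"][...]
            model.iteration = int(f.attrs["iteration"])
            model.astro_layer.running_max = float(f.attrs["running_max"])
        return model

    def state_fingerprint(self) -> tuple:
        """Hashable digest of all mutable state, for determinism checks."""
        import hashlib

        h = hashlib.sha256()
        for arr in (self.A.weights, self.E.weights, self.I.weights, self.rho, self.ybar):
            h.update(np.ascontiguousarray(arr).tobytes())
        h.update(np.float64(self.astro_layer.running_max).tobytes())
        return (self.iteration, h.hexdigest())
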