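"""Run configuration: model constants, stimulus ensemble, analysis knobs.

Every model symbol is an explicit, serialisable key so that a run is a pure
function of its config and seeds.  Configs round-trip through YAML with the
block structure ``{stimuli, lgn, model, astrocyte, homeostasis, analysis}``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .geometry import MM_PER_SHEET_UNIT


@dataclass
class StimulusParams:
    """Elongated-Gaussian training ensemble.

    Centres are uniform over the LGN-visible extent (plus ``margin`` sheet
    units on every side so stimuli may straddle the edge); orientations are
    uniform on [0, pi).  The aspect ratio must be elongated enough to carry
    an orientation signal at the scale of the afferent receptive fields.
    """

    sigma_major: float = 0.30
    sigma_minor: float = 0.10
    amplitude: float = 1.0
    margin: float = 0.25

    def validate(self) -> None:
        if not (self.sigma_major >= self.sigma_minor > 0):
            raise ValueError(
                "need sigma_major >= sigma_minor > 0, got "
                f"({self.sigma_major}, {self.sigma_minor})"
            )
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass
class LGNParams:
    """ON/OFF LGN stage: DoG receptive fields with lateral gain control.

    ``gamma_o`` scales the afferent difference-of-Gaussians drive and
    ``gamma_s`` the strength of the suppressive pool driven by neighbouring
    LGN units.  ``gain_mode`` selects how the pool acts: ``divisive``
    (contrast gain control, the default) or ``subtractive``.  ``sigma_pool``
    is the width of the suppressive pool; it defaults to ``sigma_c``.
    """

    sigma_c: float = 0.07
    sigma_s: float = 0.28
    support_radius: float | None = None  # default 3 * sigma_s
    gamma_o: float = 5.0
    gamma_s: float = 0.6
    gain_mode: str = "divisive"
    settle_steps: int = 2
    sigma_pool: float | None = None  # default sigma_c

    def validate(self) -> None:
        if not (self.sigma_s > self.sigma_c > 0):
            raise ValueError("need sigma_s > sigma_c > 0")
        if self.gain_mode not in ("divisive", "subtractive"):
            raise ValueError(f"unknown gain_mode {self.gain_mode!r}")
        if self.settle_steps < 0:
            raise ValueError("settle_steps must be >= 0")

    @property
    def effective_support(self) -> float:
        return 3.0 * self.sigma_s if self.support_radius is None else self.support_radius

    @property
    def effective_sigma_pool(self) -> float:
        return self.sigma_c if self.sigma_pool is None else self.sigma_pool


@dataclass
class HomeostasisParams:
    """Homeostatic threshold adaptation of the V1 rectifier.

    ``beta`` smooths each unit's activity trace, ``lam`` is the homeostatic
    learning rate and ``mu`` the target mean activity.  ``form`` selects the
    threshold update: ``balanced`` uses ``rho += lam * (ybar - mu)`` (the
    dimensionally consistent form, default) while ``printed`` uses
    ``rho += lam * ybar - mu``.
    """

    beta: float = 0.99
    lam: float = 0.01
    mu: float = 0.024
    form: str = "balanced"
    max_step: float | None = 0.002  # anti-windup clip on each threshold update
    rho_init: float = 0.25

    def validate(self) -> None:
        if not (0 < self.beta < 1):
            raise ValueError("beta must be in (0, 1)")
        if self.form not in ("balanced", "printed"):
            raise ValueError(f"unknown homeostasis form {self.form!r}")


@dataclass
class AstrocyteParams:
    """Astrocyte layer: disc pooling of synaptic drive, optional gap junctions.

    ``radius_mm`` is the anatomical (GFAP-marked) astrocyte radius; because
    GFAP labels only ~15% of the astrocyte volume the radius actually used
    for pooling is ``radius_mm * gfap_scale`` (default scale 2).  The pooled
    activation is rescaled into [0, 1] so the BCM threshold 1 - S stays in
    [0, 1]: by each presentation's own peak (``norm_mode="presentation"``,
    default) or by a running maximum with time constant ``norm_tau``
    presentations (``norm_mode="running"``).
    """

    radius_mm: float = 0.1125
    gfap_scale: float = 2.0
    norm_mode: str = "presentation"  # or "running"
    norm_tau: float = 100.0
    gap_junctions: bool = False
    gap_strength: float = 0.1
    gap_sigma: float = 1.0

    def validate(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if self.norm_tau <= 0:
            raise ValueError("norm_tau must be positive")
        if self.norm_mode not in ("presentation", "running"):
            raise ValueError(f"unknown norm_mode {self.norm_mode!r}")

    @property
    def scaled_radius_mm(self) -> float:
        """Effective pooling radius after GFAP correction."""
        return self.radius_mm * self.gfap_scale


@dataclass
class ModelConfig:
    """Full configuration of the astrocyte-gated GCAL model.

    Connection strengths ``p, q, r`` (afferent / lateral excitatory /
    lateral inhibitory), learning rates ``eta_A, eta_E, eta_I``, and the
    afferent and inhibitory radii ``rad_A, rad_I`` (sheet units) follow the
    standard orientation-map parameterisation.  ``variant`` selects whether
    the astrocyte input (synaptic drive) includes the inhibitory,
    GABA-mediated term (``full``) or omits it (``no_gaba``).
    """

    # sheet geometry
    extent: float = 1.0
    density: int = 48
    mm_per_unit: float = MM_PER_SHEET_UNIT

    # connection strengths and radii
    p: float = 1.5
    q: float = 2.1
    r: float = 1.4
    eta_A: float = 0.1
    eta_E: float = 0.3
    eta_I: float = 0.3
    rad_A: float = 0.27
    rad_I: float = 0.22

    # dynamics
    settling_steps: int = 16
    variant: str = "full"
    learn_per_step: bool = False
    # upper saturation of the rectifier; keeps rates on the same [0, 1] scale
    # as the astrocytic BCM threshold and bounds the recurrent dynamics
    # (set to None for a pure half-wave rectifier)
    y_max: float | None = 1.0

    # lateral-excitatory clipping: E entries live in [0, e_max_scale / n_kernel]
    e_max_scale: float = 4.0
    # divisively renormalise E after each BCM step (the BCM rule then shapes
    # the lag profile while total lateral-excitatory strength stays fixed)
    e_normalize: bool = True

    # weight initialisation: Gaussian profile (sigma as a fraction of each
    # projection's radius) plus uniform noise
    init_sigma_frac_A: float = 0.5
    init_sigma_frac_E: float = 0.3
    init_sigma_frac_I: float = 10.0  # effectively flat over the inhibitory disc
    init_noise_A: float = 0.8
    init_noise_lat: float = 0.1

    seed: int = 0

    stimuli: StimulusParams = field(default_factory=StimulusParams)
    lgn: LGNParams = field(default_factory=LGNParams)
    homeostasis: HomeostasisParams = field(default_factory=HomeostasisParams)
    astrocyte: AstrocyteParams = field(default_factory=AstrocyteParams)

    def validate(self) -> None:
        if self.p <= 0:
            raise ValueError("p must be positive")
        for name in ("q", "r"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("eta_A", "eta_E", "eta_I"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.rad_A <= 0 or self.rad_I <= 0:
            raise ValueError("radii must be positive")
        if self.variant not in ("full", "no_gaba"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.settling_steps < 1:
            raise ValueError("settling_steps must be >= 1")
        self.stimuli.validate()
        self.lgn.validate()
        self.homeostasis.validate()
        self.astrocyte.validate()

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return {
            "stimuli": d.pop("stimuli"),
            "lgn": d.pop("lgn"),
            "homeostasis": d.pop("homeostasis"),
            "astrocyte": d.pop("astrocyte"),
            "model": d,
        }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ModelConfig":
        data = dict(data)
        kwargs: dict[str, Any] = dict(data.get("model", {}))
        for key, sub_cls in (
            ("stimuli", StimulusParams),
            ("lgn", LGNParams),
            ("homeostasis", HomeostasisParams),
            ("astrocyte", AstrocyteParams),
        ):
            if key in data:
                kwargs[key] = sub_cls(**data[key])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def replace(self, **kwargs: Any) -> "ModelConfig":
        return dataclasses.replace(self, **kwargs)
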