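"""Orientation-map measurement by grating probing with frozen plasticity.

Preference and selectivity are estimated per node from settled responses to
full-field sine gratings at several orientations and phases: the response at
each orientation is the maximum over phases, and preference/selectivity come
from the orientation vector sum in the doubled-angle domain.  Both the
neuronal sheet (rates ``y``) and the astrocyte sheet (activation ``S``) can
be mapped; probing never mutates weights or adaptive state.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .lgn import dog_transfer_peak
from .model import AstroGCALModel
from .stimuli import render_grating

NEURONAL, ASTROCYTE = "neuronal", "astrocyte"


class DeadMapError(RuntimeError):
    """Raised when every node gives zero response at every orientation."""


@dataclass
class OrientationMap:
    """Per-node preferred orientation in [0, pi) and selectivity."""

    preference: np.ndarray
    selectivity: np.ndarray
    layer: str = NEURONAL
    iteration: int = 0
    orientations: np.ndarray | None = None  # probe angles, radians
    responses: np.ndarray | None = None  # (n_orientations, n, n)

    def __post_init__(self) -> None:
        if self.preference.shape != self.selectivity.shape:
            raise ValueError("preference and selectivity must share a shape")
        if not np.all(np.isfinite(self.selectivity)):
            raise ValueError("selectivity must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.preference.shape

    def response_at(self, angle: float, atol: float = 1e-9) -> np.ndarray:
        """Stored response field at a probe orientation (radians)."""
        if self.orientations is None or self.responses is None:
            raise ValueError("this map carries no stored responses")
        diff = np.abs((self.orientations - angle + np.pi / 2) % np.pi - np.pi / 2)
        idx = int(np.argmin(diff))
        if diff[idx] > atol:
            raise KeyError(f"no probe orientation near {angle} rad")
        return self.responses[idx]

    def save(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("preference", data=self.preference)
            f.create_dataset("selectivity", data=self.selectivity)
            if self.responses is not None:
                f.create_dataset("responses", data=self.responses)
                f.create_dataset("orientations", data=self.orientations)
            f.attrs["layer"] = self.layer
            f.attrs["iteration"] = self.iteration

    @classmethod
    def load(cls, path: str | Path) -> "OrientationMap":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                preference=f["preference"][...],
                selectivity=f["selectivity"][...],
                layer=str(f.attrs["layer"]),
                iteration=int(f.attrs["iteration"]),
                orientations=f["orientations"][...] if "orientations" in f else None,
                responses=f["responses"][...] if "responses" in f else None,
            )


def preference_from_responses(
    responses: np.ndarray, orientations: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vector-sum orientation preference and selectivity.

    ``preference = 0.5 * arg(sum_k r_k exp(2 i phi_k))`` folded to [0, pi);
    ``selectivity = |sum_k r_k exp(2 i phi_k)| / sum_k r_k``.  Nodes with no
    response at any orientation get preference 0 and selectivity 0.
    """
    phases = np.exp(2j * orientations)
    z = np.tensordot(phases, responses, axes=(0, 0))
    total = responses.sum(axis=0)
    ok = total > 0
    selectivity = np.zeros_like(total)
    preference = np.zeros_like(total)
    selectivity[ok] = np.abs(z[ok]) / total[ok]
    preference[ok] = (np.angle(z[ok]) / 2.0) % np.pi
    # untuned nodes (vector sum at rounding level): preference pinned to 0
    untuned = selectivity < 1e-12
    preference[untuned] = 0.0
    return preference, selectivity


def probe_orientation_map(
    model: AstroGCALModel,
    n_orientations: int = 8,
    n_phases: int = 4,
    layer: str = NEURONAL,
    spatial_freq: float | None = None,
    amplitude: float = 0.2,
) -> OrientationMap:
    """Measure an orientation map from the current model weights.

    Probes with ``n_orientations`` grating angles spanning [0, pi) and
    ``n_phases`` phases each, pooling over phases by the maximum settled
    response.  ``spatial_freq`` defaults to the peak of the LGN DoG transfer
    function (the afferent spatial scale).  The default probe contrast is
    low (``amplitude=0.2``): it keeps the recurrent sheet in its graded
    regime, where the measured preference map is reproducible across probe
    parameterisations (phase count, orientation count); at full contrast
    the settled response is dominated by a multistable blob lattice and the
    measured map is not a stable property of the model.
    """
    if n_orientations < 4:
        raise ValueError("need n_orientations >= 4")
    if n_phases < 2:
        raise ValueError("need n_phases >= 2")
    if layer not in (NEURONAL, ASTROCYTE):
        raise ValueError(f"unknown layer {layer!r}")
    if spatial_freq is None:
        spatial_freq = dog_transfer_peak(model.config.lgn.sigma_c, model.config.lgn.sigma_s)

    angles = np.arange(n_orientations) * np.pi / n_orientations
    n = model.cortex_geom.n

    def _responses(amp: float) -> np.ndarray:
        resp = np.zeros((n_orientations, n, n))
        for k, phi in enumerate(angles):
            best = np.zeros((n, n))
            for j in range(n_phases):
                phase = 2.0 * np.pi * j / n_phases
                retina = render_grating(model.retina_geom, phi, spatial_freq, phase, amp)
                result = model.respond(retina, learn=False)
                field = result.y if layer == NEURONAL else result.astro.S
                np.maximum(best, field, out=best)
            resp[k] = best
        return resp

    # a fully sub-threshold sheet (e.g. an untrained model) is re-probed at
    # doubled contrast before the map is declared dead
    responses = _responses(amplitude)
    while not np.any(responses) and amplitude < 1.0:
        amplitude = min(2.0 * amplitude, 1.0)
        responses = _responses(amplitude)
    if not np.any(responses):
        raise DeadMapError(f"all-zero {layer} responses at every probe orientation")
    preference, selectivity = preference_from_responses(responses, angles)
    return OrientationMap(
        preference=preference,
        selectivity=selectivity,
        layer=layer,
        iteration=model.iteration,
        orientations=angles,
        responses=responses,
    )
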