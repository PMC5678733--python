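"""Training orchestration: runs, probe schedules and the astrocyte-radius sweep.

A run is a pure function of its config and seeds: the same inputs give
bitwise-identical checkpoints.  The sweep varies the astrocyte radius over
several seeds, analyses the final neuronal and astrocyte maps of every cell
and aggregates one summary row per (radius, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import analyze_map, similarity_curve, stability_index
from .config import ModelConfig
from .model import AstroGCALModel
from .probe import ASTROCYTE, NEURONAL, OrientationMap, probe_orientation_map

logger = logging.getLogger(__name__)

#: Probe schedule used in the radius study.
DEFAULT_PROBE_ITERATIONS = (250, 500, 750, 1000, 2500, 5000, 7500, 10000)

#: Anatomical astrocyte radii (mm, GFAP-marked) of the radius study.
DEFAULT_SWEEP_RADII_MM = (0.015, 0.0375, 0.075, 0.1125, 0.15, 0.1875)


@dataclass
class RunSchedule:
    """Iteration budget, probe points, sweep radii and seeds for a study."""

    total_iterations: int = 10000
    probe_iterations: tuple[int, ...] = DEFAULT_PROBE_ITERATIONS
    sweep_radii_mm: tuple[float, ...] = DEFAULT_SWEEP_RADII_MM
    seeds: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self) -> None:
        probes = tuple(sorted(self.probe_iterations))
        if any(p > self.total_iterations for p in probes):
            probes = tuple(p for p in probes if p <= self.total_iterations)
        object.__setattr__(self, "probe_iterations", probes)
        if any(r <= 0 for r in self.sweep_radii_mm):
            raise ValueError("sweep radii must be positive")


@dataclass
class RunResult:
    """Final model plus the orientation maps probed during training."""

    model: AstroGCALModel
    maps: dict[int, dict[str, OrientationMap]] = field(default_factory=dict)

    def final_map(self, layer: str = NEURONAL) -> OrientationMap:
        if not self.maps:
            raise ValueError("run has no probed maps")
        return self.maps[max(self.maps)][layer]


def train(
    config: ModelConfig,
    schedule: RunSchedule,
    out_dir: str | Path | None = None,
    probe_kwargs: dict | None = None,
) -> RunResult:
    """Train a model, probing both layers at the scheduled iterations.

    Probing freezes plasticity and does not mutate the model.  With
    ``total_iterations == 0`` the probed map reflects the random initial
    weights.  Checkpoints and maps are written under ``out_dir`` if given.
    """
    probe_kwargs = probe_kwargs or {}
    model = AstroGCALModel(config)
    result = RunResult(model=model)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")

    def _probe(it: int) -> None:
        maps = {
            NEURONAL: probe_orientation_map(model, layer=NEURONAL, **probe_kwargs),
            ASTROCYTE: probe_orientation_map(model, layer=ASTROCYTE, **probe_kwargs),
        }
        result.maps[it] = maps
        if out is not None:
            for layer, m in maps.items():
                m.save(out / f"map_{layer}_{it:06d}.h5")

    points = set(schedule.probe_iterations)
    if schedule.total_iterations == 0:
        _probe(0)
    log_rows = []
    for it in range(1, schedule.total_iterations + 1):
        pres = model.present()
        if it % 250 == 0 or it == schedule.total_iterations:
            log_rows.append(
                {
                    "iteration": it,
                    "mean_activity": float(pres.y.mean()),
                    "mean_rho": float(model.rho.mean()),
                    "mean_E_sum": float(model.E.weights.sum(axis=1).mean()),
                    "E_mass_beyond_R_astro": model.E.mass_beyond(
                        model.astro_layer.radius_px
                    ),
                    "n_redrawn": model.n_redrawn,
                }
            )
        if it in points:
            _probe(it)
    if out is not None:
        model.save_checkpoint(out / "checkpoint.h5")
        with open(out / "run_log.jsonl", "w") as fh:
            for row in log_rows:
                fh.write(json.dumps(row) + "\n")
    return result


def analyze_run(
    result: RunResult,
    similarity_radii_mm: tuple[float, ...] = (0.125, 0.25, 0.5),
) -> dict:
    """Full analysis of a finished run's final maps.

    Returns the summary-row dict used by the sweep: hypercolumn width,
    pinwheel count and density, the neuronal/astrocyte stability index and
    the local-similarity curve of the neuronal map.
    """
    model = result.model
    extent_mm = model.cortex_geom.extent_mm
    neuro = result.final_map(NEURONAL)
    astro = result.final_map(ASTROCYTE)
    ana = analyze_map(neuro, extent_mm)
    mm_per_px = extent_mm / neuro.shape[0]
    curve = similarity_curve(neuro.preference, np.asarray(similarity_radii_mm), mm_per_px)
    return {
        "radius_mm": model.config.astrocyte.radius_mm,
        "seed": model.config.seed,
        "lambda_mm": ana.hypercolumn_mm,
        "zeta": ana.zeta,
        "n_pinwheels": ana.n_pinwheels,
        "pw_per_hc": ana.pw_per_hypercolumn,
        "si_neuro_astro": stability_index(neuro.preference, astro.preference),
        "mean_local_angle_deg": ana.mean_local_angle_deg,
        "similarity_curve": curve,
        "analysis": ana,
        "maps": {NEURONAL: neuro, ASTROCYTE: astro},
    }


SWEEP_COLUMNS = [
    "radius_mm",
    "seed",
    "lambda_mm",
    "n_pinwheels",
    "pw_per_hc",
    "si_neuro_astro",
    "mean_local_angle_deg",
]


def run_sweep(
    base_config: ModelConfig,
    schedule: RunSchedule,
    out_dir: str | Path | None = None,
    probe_kwargs: dict | None = None,
    keep_details: bool = False,
) -> pd.DataFrame:
    """Sweep the astrocyte radius over seeds and summarise every cell.

    Each (radius, seed) cell trains a fresh model and contributes one row;
    a failed cell is recorded with NaNs and an error message, and the sweep
    continues.  The table is also written as CSV under ``out_dir`` if given.
    """
    if len(schedule.sweep_radii_mm) < 1 or len(schedule.seeds) < 1:
        raise ValueError("sweep needs at least one radius and one seed")
    rows = []
    details = []
    for radius in schedule.sweep_radii_mm:
        for seed in schedule.seeds:
            cfg = base_config.replace(
                seed=seed,
                astrocyte=base_config.astrocyte.__class__(
                    **{**base_config.astrocyte.__dict__, "radius_mm": radius}
                ),
            )
            try:
                result = train(cfg, schedule, probe_kwargs=probe_kwargs)
                summary = analyze_run(result)
                rows.append({c: summary[c] for c in SWEEP_COLUMNS} | {"error": ""})
                if keep_details:
                    details.append(summary)
            except Exception as exc:  # cell failure must not kill the sweep
                logger.warning("sweep cell (R=%s, seed=%s) failed: %s", radius, seed, exc)
                rows.append(
                    {c: np.nan for c in SWEEP_COLUMNS}
                    | {"radius_mm": radius, "seed": seed, "error": str(exc)}
                )
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "sweep_summary.csv", index=False)
    if keep_details:
        table.attrs["details"] = details
    return table
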