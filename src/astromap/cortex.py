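"""V1 rate dynamics: recurrent settling, synaptic drive, homeostasis.

Each presentation, the cortical sheet settles from rest under a fixed LGN
input: ``y(t) = f(p*A.L + q*E.y(t-1) - r*I.y(t-1))`` with ``f`` a half-wave
rectifier with an adaptive per-unit threshold ``rho``.  The pre-rectification
sum is the synaptic drive ``gs`` that feeds the astrocyte layer.  After
settling, each unit's smoothed activity trace updates its threshold
homeostatically toward a target mean activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelConfig
from .projections import ProjectionField, extract_patches


@dataclass
class V1State:
    """Firing rates and homeostatic state of the cortical sheet."""

    y: np.ndarray  # settled firing rates, >= 0
    gs: np.ndarray  # synaptic drive (pre-rectification sum) at the final step
    rho: np.ndarray  # adaptive rectifier thresholds
    ybar: np.ndarray  # smoothed activity traces


class DivergenceError(RuntimeError):
    """Raised when settling produces non-finite activity."""


def afferent_drive(
    A: ProjectionField, lgn_on: np.ndarray, lgn_off: np.ndarray
) -> np.ndarray:
    """Per-unit afferent input ``sum_ab A_ij,ab L_ab`` over both channels."""
    return A.drive_field(lgn_on, valid=True, channel=0) + A.drive_field(
        lgn_off, valid=True, channel=1
    )


def lateral_terms(
    y: np.ndarray, E: ProjectionField, I: ProjectionField
) -> tuple[np.ndarray, np.ndarray]:
    """Excitatory and inhibitory lateral drives for the current rates."""
    return E.drive_field(y), I.drive_field(y)


def synaptic_drive(
    aff: np.ndarray,
    y: np.ndarray,
    E: ProjectionField,
    I: ProjectionField,
    config: ModelConfig,
    variant: str | None = None,
) -> np.ndarray:
    """Synaptic drive ``gs`` for the given rates (flat, per unit).

    The ``full`` variant is ``p*A.L + q*E.y - r*I.y``; the ``no_gaba``
    variant omits the inhibitory (GABA-mediated) term.  The full variant is
    exactly the pre-rectification sum used inside settling (shared code
    path).
    """
    variant = config.variant if variant is None else variant
    exc, inh = lateral_terms(y, E, I)
    if variant == "full":
        return config.p * aff + config.q * exc - config.r * inh
    if variant == "no_gaba":
        return config.p * aff + config.q * exc
    raise ValueError(f"unknown variant {variant!r}")


def v1_settle_from_aff(
    aff: np.ndarray,
    E: ProjectionField,
    I: ProjectionField,
    rho: np.ndarray,
    config: ModelConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Settle the cortical sheet given a precomputed afferent drive.

    Rates start from zero at stimulus onset and iterate the rectified
    recurrence for ``config.settling_steps`` steps; the rectifier saturates
    at ``config.y_max`` (if set), bounding the recurrent loop.  Returns the settled
    rates ``y`` and the final-step synaptic drive ``gs`` (both as 2-D
    fields).  Raises :class:`DivergenceError` on non-finite activity.
    """
    n = int(round(np.sqrt(aff.size)))
    shape = (n, n)
    rho_flat = np.broadcast_to(np.asarray(rho, dtype=float).ravel(), aff.shape)
    y = np.zeros(shape)
    gs = np.asarray(aff) * config.p
    y_max = np.inf if config.y_max is None else config.y_max
    for _ in range(config.settling_steps):
        gs = synaptic_drive(aff, y, E, I, config, variant="full")
        y = np.clip(gs - rho_flat, 0.0, y_max).reshape(shape)
    if not np.all(np.isfinite(y)):
        raise DivergenceError(
            "non-finite V1 activity during settling; check strengths "
            f"p={config.p}, q={config.q}, r={config.r} and e_max_scale="
            f"{config.e_max_scale}"
        )
    return y, gs.reshape(shape)


def v1_settle(
    lgn_on: np.ndarray,
    lgn_off: np.ndarray,
    A: ProjectionField,
    E: ProjectionField,
    I: ProjectionField,
    rho: np.ndarray,
    config: ModelConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Settle the cortical sheet under a fixed LGN input (see above)."""
    aff = afferent_drive(A, lgn_on, lgn_off)
    return v1_settle_from_aff(aff, E, I, rho, config)


def homeostatic_update(
    y: np.ndarray,
    ybar: np.ndarray,
    rho: np.ndarray,
    beta: float,
    lam: float,
    mu: float,
    form: str = "balanced",
    max_step: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One homeostatic step: smooth the activity trace, adapt the threshold.

    ``ybar' = (1 - beta) y + beta ybar``.  The threshold update is either
    ``rho' = rho + lam * (ybar' - mu)`` (``balanced``) or
    ``rho' = rho + lam * ybar' - mu`` (``printed``); both drive each unit's
    long-run mean activity toward the target ``mu``.  With ``max_step`` the
    per-presentation threshold change is clipped to ``[-max_step, max_step]``
    (anti-windup: brief saturated bursts cannot run the threshold far past
    the reach of the afferent drive).
    """
    ybar_new = (1.0 - beta) * y + beta * ybar
    if form == "balanced":
        delta = lam * (ybar_new - mu)
    elif form == "printed":
        delta = lam * ybar_new - mu
    else:
        raise ValueError(f"unknown homeostasis form {form!r}")
    if max_step is not None:
        delta = np.clip(delta, -max_step, max_step)
    return ybar_new, rho + delta
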