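"""Figure helpers: HSV orientation maps and spectrum-fit overlays."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import hsv_to_rgb

from .analysis import PinwheelSet, SpectrumFit
from .probe import OrientationMap


def map_to_rgb(omap: OrientationMap) -> np.ndarray:
    """HSV rendering: hue = preference, value = normalised selectivity."""
    hue = omap.preference / np.pi
    sel = omap.selectivity
    value = sel / sel.max() if sel.max() > 0 else np.zeros_like(sel)
    hsv = np.stack([hue, np.ones_like(hue), value], axis=-1)
    return hsv_to_rgb(hsv)


def save_map_png(
    omap: OrientationMap,
    path: str | Path,
    pinwheels: PinwheelSet | None = None,
    title: str | None = None,
) -> None:
    """Write an orientation map (optionally with pinwheel markers) to PNG."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(map_to_rgb(omap), origin="lower", interpolation="nearest")
    if pinwheels is not None and pinwheels.count:
        pos = pinwheels.charges > 0
        ax.plot(pinwheels.centers[pos, 1], pinwheels.centers[pos, 0], "w+", ms=6)
        ax.plot(pinwheels.centers[~pos, 1], pinwheels.centers[~pos, 0], "wx", ms=5)
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title, fontsize=9)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def save_spectrum_png(fit: SpectrumFit, path: str | Path) -> None:
    """Radial power spectrum with the fitted peak curve and position."""
    fig, ax = plt.subplots(figsize=(4.5, 3))
    ax.plot(fit.k, fit.power, "k.-", lw=0.8, label="P(k)")
    if fit.converged:
        kk = np.linspace(fit.k[1], fit.k[-1], 400)
        from .analysis import _peak_model

        ax.plot(kk, _peak_model(kk, *fit.params), "r-", lw=1.2, label="fit")
    ax.axvline(fit.zeta, color="b", ls="--", lw=0.8, label=f"zeta = {fit.zeta:.2f}")
    ax.set_xlabel("k (cycles / map extent)")
    ax.set_ylabel("radial power")
    ax.legend(fontsize=8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
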