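"""Discretized 2-D neural sheets and the sheet-unit <-> millimetre mapping.

The model is defined on square sheets of nodes.  Distances and radii are
expressed in *sheet units*; the cortical sheet of extent 1.0 sheet unit
represents a 3 x 3 mm patch of tissue, so 1 sheet unit = 3 mm by default.
Retinal/LGN sheets are larger than the cortical sheet so that every cortical
unit, including those at the edge, has a fully supported receptive field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Default conversion: cortical extent 1.0 sheet units spans a 3 mm patch.
MM_PER_SHEET_UNIT = 3.0


@dataclass(frozen=True)
class SheetGeometry:
    """A square sheet of nodes with uniform density.

    Parameters
    ----------
    extent : float
        Side length of the sheet in sheet units.
    density : int
        Nodes per sheet unit along each axis.  The node count per axis is
        ``round(extent * density)``.
    mm_per_unit : float
        Millimetres of tissue per sheet unit (strictly positive).
    """

    extent: float
    density: int
    mm_per_unit: float = MM_PER_SHEET_UNIT

    def __post_init__(self) -> None:
        if self.extent <= 0:
            raise ValueError(f"extent must be positive, got {self.extent}")
        if self.density < 8:
            raise ValueError(f"density must be >= 8, got {self.density}")
        if self.mm_per_unit <= 0:
            raise ValueError("mm_per_unit must be positive")

    @property
    def n(self) -> int:
        """Number of nodes per axis."""
        return int(round(self.extent * self.density))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n, self.n)

    @property
    def spacing(self) -> float:
        """Node spacing in sheet units."""
        return 1.0 / self.density

    @property
    def extent_mm(self) -> float:
        return self.extent * self.mm_per_unit

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Node-centre coordinates (x, y) in sheet units, centred on 0.

        Returns two 2-D arrays of shape ``(n, n)``; ``x`` varies along the
        column axis and ``y`` along the row axis.
        """
        n = self.n
        axis = (np.arange(n) - (n - 1) / 2.0) * self.spacing
        y, x = np.meshgrid(axis, axis, indexing="ij")
        return x, y

    def mm_to_sheet(self, mm: float) -> float:
        return mm / self.mm_per_unit

    def sheet_to_mm(self, sheet_units: float) -> float:
        return sheet_units * self.mm_per_unit

    def to_pixels(self, sheet_units: float) -> float:
        """Convert a length in sheet units to a length in node spacings."""
        return sheet_units * self.density

    def expanded(self, pad_pixels: int) -> "SheetGeometry":
        """A concentric sheet enlarged by ``pad_pixels`` nodes on every side."""
        n_new = self.n + 2 * pad_pixels
        return SheetGeometry(n_new / self.density, self.density, self.mm_per_unit)
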