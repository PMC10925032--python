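"""Raster containers and grid geometry.

All spatial layers in a run live on one shared grid: same shape, same
affine transform, same CRS label. Mixing grids is an error, never an
implicit resample.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

__all__ = ["Affine", "Raster", "GridAlignmentError", "FLOAT_NODATA", "INT_NODATA"]

FLOAT_NODATA = -9999.0
INT_NODATA = -1


class GridAlignmentError(ValueError):
    """Two layers that must share a grid do not."""


class Affine(NamedTuple):
    """Row-major affine transform, origin top-left.

    World coordinates of the centre of cell (row, col):
      x = a*col + b*row + c
      y = d*col + e*row + f
    For an axis-aligned grid b = d = 0, a = cell width, e = -cell height.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def from_origin(cls, x0: float, y0: float, dx: float, dy: float) -> "Affine":
        """North-up grid with top-left corner (x0, y0) and cell size dx × dy."""
        return cls(dx, 0.0, x0, 0.0, -dy, y0)

    @property
    def cell_width(self) -> float:
        return abs(self.a)

    @property
    def cell_height(self) -> float:
        return abs(self.e)


@dataclass
class Raster:
    """A single-band 2-D grid with geometry and a nodata sentinel.

    ``values`` is float64 (or an integer dtype for categorical layers) in
    memory; disk writers cast to float32/int32. Cells equal to ``nodata``
    are outside the domain.
    """

    values: np.ndarray
    transform: Affine
    crs_label: str = "local-albers-equal-area"
    nodata: float = FLOAT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"raster must be 2-D, got shape {self.values.shape}")
        if not isinstance(self.transform, Affine):
            self.transform = Affine(*self.transform)
        finite = np.isfinite(self.values) | (self.values == self.nodata)
        if not finite.all():
            raise ValueError("raster holds non-finite values outside nodata")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of in-domain cells."""
        return self.values != self.nodata

    def filled(self, fill: float = 0.0) -> np.ndarray:
        """Values with nodata replaced by ``fill`` (float64 copy)."""
        out = self.values.astype(np.float64, copy=True)
        out[~self.valid] = fill
        return out

    def with_values(self, values: np.ndarray, nodata: float | None = None) -> "Raster":
        """New raster on the same grid carrying ``values``."""
        return replace(
            self, values=values, nodata=self.nodata if nodata is None else nodata
        )

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and self.transform == other.transform
            and self.crs_label == other.crs_label
        )


def require_aligned(*rasters: Raster) -> None:
    """Raise :class:`GridAlignmentError` unless all layers share one grid."""
    ref = rasters[0]
    for r in rasters[1:]:
        if not ref.same_grid(r):
            raise GridAlignmentError(
                "grid mismatch: "
                f"shape {ref.shape} / transform {ref.transform} / crs {ref.crs_label!r}"
                f" vs shape {r.shape} / transform {r.transform} / crs {r.crs_label!r}"
            )
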