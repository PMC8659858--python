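"""North-up raster grids with center-of-pixel sampling.

Conventions used across the package: projected metre coordinates, x east /
y north; row 0 is the northern edge; the value of cell (row, col) sits at
the pixel center ``x = x0 + (col + 0.5) * px``, ``y = y0 - (row + 0.5) * px``
where ``(x0, y0)`` is the north-west corner of the grid.

On-disk dialect: a NumPy ``.npy`` binary grid next to a JSON sidecar
``{"origin": [x0, y0], "pixel_size": px, "shape": [nrows, ncols]}`` (plus
``"bands"`` for multi-band rasters).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Grid", "Raster", "horn_slope_deg"]


@dataclass
class Grid:
    """Single-band raster (DEM, CHM, slope...)."""

    data: np.ndarray          # (nrows, ncols), float
    origin: tuple[float, float]  # (x west edge, y north edge)
    pixel_size: float            # metres

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Grid data must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the outer grid edges."""
        nr, nc = self.data.shape
        x0, y0 = self.origin
        return x0, x0 + nc * self.pixel_size, y0 - nr * self.pixel_size, y0

    def contains(self, x: float, y: float) -> bool:
        xmin, xmax, ymin, ymax = self.extent
        return (xmin <= x <= xmax) and (ymin <= y <= ymax)

    def _frac_index(self, x, y):
        """Fractional (row, col) of a point in pixel-center coordinates."""
        x0, y0 = self.origin
        col = (np.asarray(x, dtype=float) - x0) / self.pixel_size - 0.5
        row = (y0 - np.asarray(y, dtype=float)) / self.pixel_size - 0.5
        return row, col

    def sample(self, x, y):
        """Bilinear sample at projected coordinates; clamped at the edges.

        Raises ValueError when any query point falls outside the grid extent.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        xmin, xmax, ymin, ymax = self.extent
        if np.any(x < xmin) or np.any(x > xmax) or np.any(y < ymin) or np.any(y > ymax):
            raise ValueError("sample point outside grid extent")
        row, col = self._frac_index(x, y)
        nr, nc = self.data.shape
        row = np.clip(row, 0.0, nr - 1.0)
        col = np.clip(col, 0.0, nc - 1.0)
        r0 = np.clip(np.floor(row).astype(int), 0, nr - 2) if nr > 1 else np.zeros_like(row, int)
        c0 = np.clip(np.floor(col).astype(int), 0, nc - 2) if nc > 1 else np.zeros_like(col, int)
        fr = row - r0
        fc = col - c0
        d = self.data
        if nr == 1:
            fr = np.zeros_like(fr)
        if nc == 1:
            fc = np.zeros_like(fc)
        r1 = np.minimum(r0 + 1, nr - 1)
        c1 = np.minimum(c0 + 1, nc - 1)
        val = ((1 - fr) * (1 - fc) * d[r0, c0] + (1 - fr) * fc * d[r0, c1]
               + fr * (1 - fc) * d[r1, c0] + fr * fc * d[r1, c1])
        return float(val) if val.ndim == 0 else val

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.data)
        sidecar = {"origin": list(self.origin), "pixel_size": self.pixel_size,
                   "shape": list(self.data.shape)}
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "Grid":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        data = np.load(path.with_suffix(".npy"))
        return cls(data=data, origin=tuple(meta["origin"]), pixel_size=meta["pixel_size"])


@dataclass
class Raster:
    """Multi-band raster (RGB tiles): data shaped (bands, nrows, ncols)."""

    data: np.ndarray
    origin: tuple[float, float]
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("Raster data must be 3-D (bands, rows, cols)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]

    def band(self, i: int) -> np.ndarray:
        return self.data[i]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.data)
        sidecar = {"origin": list(self.origin), "pixel_size": self.pixel_size,
                   "shape": list(self.data.shape[1:]), "bands": self.data.shape[0]}
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "Raster":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        data = np.load(path.with_suffix(".npy"))
        return cls(data=data, origin=tuple(meta["origin"]), pixel_size=meta["pixel_size"])


def horn_slope_deg(grid: Grid) -> np.ndarray:
    """Slope in degrees by Horn's 3x3 weighted finite differences.

    Edge cells use replicated borders; exact for planar surfaces.
    """
    z = grid.data
    zp = np.pad(z, 1, mode="edge")
    px = grid.pixel_size
    a = zp[:-2, :-2]; b = zp[:-2, 1:-1]; c = zp[:-2, 2:]
    d = zp[1:-1, :-2];                    f = zp[1:-1, 2:]
    g = zp[2:, :-2];  h = zp[2:, 1:-1];  i = zp[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * px)
    # row index grows southwards, so dz/dy(north) flips sign of the row diff
    dzdy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8.0 * px)
    return np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
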