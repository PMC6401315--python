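"""Minimal georeferenced raster container.

A :class:`Raster` couples a numpy grid (band x row x col, or row x col for a
single band) with a six-term affine transform mapping pixel indices to world
coordinates, and a nodata sentinel.  The convention is the usual north-up GIS
one: row-major storage, origin at the top-left corner, world coordinates in
centimetres here (elevations as well as ground distances), and a cell's value
referring to its centre.

Single-band rasters round-trip through the ESRI ASCII grid text format
(``.asc``); multi-band rasters are written as one ``.asc`` per band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = ["Affine", "Raster", "read_ascii_grid", "write_ascii_grid"]


@dataclass(frozen=True)
class Affine:
    """Affine pixel->world map: x = a*col + b*row + c, y = d*col + e*row + f."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    def __post_init__(self) -> None:
        if abs(self.a * self.e - self.b * self.d) < 1e-300:
            raise ValueError("affine transform is singular")

    @classmethod
    def north_up(cls, origin_x: float, origin_y: float, pixel_size: float) -> "Affine":
        """Square-pixel, axis-aligned transform with y decreasing down rows."""
        return cls(pixel_size, 0.0, origin_x, 0.0, -pixel_size, origin_y)

    def xy(self, row, col):
        """World coordinates of the centre of cell (row, col)."""
        col = np.asarray(col, dtype=float) + 0.5
        row = np.asarray(row, dtype=float) + 0.5
        return self.a * col + self.b * row + self.c, self.d * col + self.e * row + self.f

    def index(self, x, y):
        """Cell (row, col) containing world point (x, y)."""
        det = self.a * self.e - self.b * self.d
        dx = np.asarray(x, dtype=float) - self.c
        dy = np.asarray(y, dtype=float) - self.f
        col = (self.e * dx - self.b * dy) / det
        row = (-self.d * dx + self.a * dy) / det
        return np.floor(row).astype(int), np.floor(col).astype(int)


@dataclass
class Raster:
    """Grid of values with an affine georeference and a nodata sentinel."""

    values: np.ndarray
    transform: Affine
    nodata: float = -9999.0
    units: str = "cm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (2, 3):
            raise ValueError("raster values must be 2-D (band) or 3-D (bands)")

    @property
    def n_bands(self) -> int:
        return 1 if self.values.ndim == 2 else self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[-2:]

    def band(self, i: int) -> np.ndarray:
        return self.values if self.values.ndim == 2 else self.values[i]

    def mask_valid(self) -> np.ndarray:
        """Boolean grid, True where every band holds data."""
        if self.values.ndim == 2:
            return self.values != self.nodata
        return np.all(self.values != self.nodata, axis=0)

    def same_grid(self, other: "Raster") -> bool:
        return self.shape == other.shape and self.transform == other.transform

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """World (x, y) arrays of every cell centre, each of grid shape."""
        nrow, ncol = self.shape
        rows, cols = np.meshgrid(np.arange(nrow), np.arange(ncol), indexing="ij")
        return self.transform.xy(rows, cols)

    def copy_with(self, values: np.ndarray) -> "Raster":
        return Raster(values, self.transform, nodata=self.nodata, units=self.units)

    def write(self, path: str | Path) -> list[Path]:
        """Write as ESRI ASCII grid(s); one file per band for multi-band."""
        path = Path(path)
        if self.values.ndim == 2:
            write_ascii_grid(path, self)
            return [path]
        out = []
        for i in range(self.n_bands):
            p = path.with_name(f"{path.stem}_band{i + 1}{path.suffix or '.asc'}")
            write_ascii_grid(p, self.copy_with(self.values[i]))
            out.append(p)
        return out


def write_ascii_grid(path: str | Path, raster: Raster) -> None:
    if raster.values.ndim != 2:
        raise ValueError("ASCII grid holds a single band")
    t = raster.transform
    if t.b != 0 or t.d != 0 or t.a != -t.e:
        raise ValueError("ASCII grid requires square, axis-aligned pixels")
    nrow, ncol = raster.shape
    # ESRI convention: (xllcorner, yllcorner) is the lower-left grid corner.
    yll = t.f + t.e * nrow
    header = (
        f"ncols {ncol}\n"
        f"nrows {nrow}\n"
        f"xllcorner {t.c!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {t.a!r}\n"
        f"NODATA_value {raster.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.values, fmt="%.6g")


def read_ascii_grid(path: str | Path) -> Raster:
    with open(path) as fh:
        hdr: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        values = np.loadtxt(fh)
    ncol, nrow = int(hdr["ncols"]), int(hdr["nrows"])
    values = values.reshape(nrow, ncol)
    cell = hdr["cellsize"]
    origin_y = hdr["yllcorner"] + cell * nrow
    transform = Affine.north_up(hdr["xllcorner"], origin_y, cell)
    return Raster(values, transform, nodata=hdr["nodata_value"])
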