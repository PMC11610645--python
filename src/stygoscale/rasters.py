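"""Planar rasters and their text I/O.

A :class:`Raster` is a rectangular grid of cells on a single planar
coordinate system in meters.  Row 0 is the northernmost row; cell values
are looked up at cell centers; cells are half-open intervals
``[edge, edge + resolution)`` from the south-west origin.

Rasters are read and written as ESRI ASCII grids (``.asc``), a plain-text
interchange format understood by all common GIS software.  Categorical
land-use rasters carry 8-bit class codes with a sidecar class-map text
file (``code,name`` per line).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ClassificationError, GeometryError

#: Canonical land-use classes, in code order 0..4.
CLASSES = ("forest", "pasture", "crop", "construction", "other")
#: name -> integer code
CLASS_CODES = {name: code for code, name in enumerate(CLASSES)}


@dataclass
class Raster:
    """A uniform rectangular grid of elevations or class codes.

    Parameters
    ----------
    values
        2-D array of shape ``(ny, nx)``; row 0 is the northernmost row.
    resolution
        Cell edge length in meters.
    origin_x, origin_y
        Planar coordinates (m) of the grid's south-west corner.
    """

    values: np.ndarray
    resolution: float
    origin_x: float = 0.0
    origin_y: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise GeometryError("raster values must be 2-D")
        if self.resolution <= 0:
            raise GeometryError("resolution must be positive")

    @property
    def ny(self) -> int:
        return self.values.shape[0]

    @property
    def nx(self) -> int:
        return self.values.shape[1]

    @property
    def width(self) -> float:
        """East-west extent in meters."""
        return self.nx * self.resolution

    @property
    def height(self) -> float:
        """North-south extent in meters."""
        return self.ny * self.resolution

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.values.shape == other.values.shape
            and self.resolution == other.resolution
            and self.origin_x == other.origin_x
            and self.origin_y == other.origin_y
        )

    # --- coordinate transforms -------------------------------------------
    def cell_at(self, x: float, y: float) -> tuple[int, int]:
        """Return ``(row, col)`` of the cell containing planar point (x, y)."""
        col = int(np.floor((x - self.origin_x) / self.resolution))
        row = self.ny - 1 - int(np.floor((y - self.origin_y) / self.resolution))
        if not (0 <= row < self.ny and 0 <= col < self.nx):
            raise GeometryError(f"point ({x}, {y}) outside raster extent")
        return row, col

    def cell_center(self, row, col):
        """Planar coordinates of the center(s) of cell(s) ``(row, col)``."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.origin_x + (col + 0.5) * self.resolution
        y = self.origin_y + (self.ny - row - 0.5) * self.resolution
        return x, y

    def value_at(self, x: float, y: float):
        row, col = self.cell_at(x, y)
        return self.values[row, col]


def write_ascii_grid(raster: Raster, path, fmt: str = "%.6g") -> None:
    """Write a raster as an ESRI ASCII grid."""
    path = Path(path)
    header = (
        f"ncols {raster.nx}\n"
        f"nrows {raster.ny}\n"
        f"xllcorner {raster.origin_x:.6f}\n"
        f"yllcorner {raster.origin_y:.6f}\n"
        f"cellsize {raster.resolution:.6f}\n"
        f"NODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.values, fmt=fmt)


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise GeometryError(f"grid shape {values.shape} disagrees with header")
    return Raster(
        values=values,
        resolution=header["cellsize"],
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
    )


def write_class_map(class_map: dict[int, str], path) -> None:
    with open(path, "w") as fh:
        for code, name in sorted(class_map.items()):
            fh.write(f"{code},{name}\n")


def read_class_map(path) -> dict[int, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            code, name = line.split(",")
            out[int(code)] = name
    return out


def reclassify(raw: Raster, mapping: dict[int, str]) -> Raster:
    """Collapse arbitrary integer land-use codes onto the 5 canonical classes.

    ``mapping`` sends every code present in ``raw`` to one of
    :data:`CLASSES`.  Codes without a mapping raise
    :class:`ClassificationError` listing the offenders.
    """
    values = np.asarray(raw.values)
    present = np.unique(values)
    unmapped = [int(c) for c in present if int(c) not in mapping]
    if unmapped:
        raise ClassificationError(
            f"raster codes without a class mapping: {unmapped}", unmapped
        )
    bad_targets = {v for v in mapping.values() if v not in CLASS_CODES}
    if bad_targets:
        raise ClassificationError(
            f"mapping targets outside the canonical classes: {sorted(bad_targets)}"
        )
    lut_in = np.array(sorted(mapping), dtype=values.dtype)
    lut_out = np.array([CLASS_CODES[mapping[int(c)]] for c in lut_in], dtype=np.uint8)
    idx = np.searchsorted(lut_in, values)
    out = lut_out[idx]
    return Raster(out, raw.resolution, raw.origin_x, raw.origin_y)
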