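"""Georeferenced multi-variable raster stacks.

A :class:`RasterStack` is the modelling substrate: one 2-D grid per
environmental variable on a shared geographic (lon/lat) georeference, with a
common nodata mask. Row 0 is the northernmost row. Values are stored as a
``(n_vars, n_rows, n_cols)`` float array with NaN marking nodata.

Rasters are read and written as ESRI ASCII grids (one ``.asc`` text file per
variable) with a ``stack.json`` sidecar listing the variables, so a stack round
trips through plain text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RasterStack", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class RasterStack:
    """Multi-variable environmental grid with a shared mask.

    Parameters
    ----------
    variables : list of str
        Variable names, one per band; unique.
    values : ndarray, shape (n_vars, n_rows, n_cols)
        Cell values; NaN at masked cells.
    lon_min, lon_max, lat_min, lat_max : float
        Outer edges of the grid in decimal degrees. Cell centres lie half a
        cell inside the edges; row 0 is the northernmost row.
    """

    variables: list[str]
    values: np.ndarray
    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != len(self.variables):
            raise ValueError("values must have shape (n_vars, n_rows, n_cols)")
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("variable names must be unique")
        if not (self.lon_max > self.lon_min and self.lat_max > self.lat_min):
            raise ValueError("degenerate extent")

    # -- geometry -----------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[1]

    @property
    def n_cols(self) -> int:
        return self.values.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    @property
    def cell_height_deg(self) -> float:
        return (self.lat_max - self.lat_min) / self.n_rows

    @property
    def cell_width_deg(self) -> float:
        return (self.lon_max - self.lon_min) / self.n_cols

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) centre coordinate vectors for columns and rows."""
        lon = self.lon_min + (np.arange(self.n_cols) + 0.5) * self.cell_width_deg
        lat = self.lat_max - (np.arange(self.n_rows) + 0.5) * self.cell_height_deg
        return lon, lat

    def rowcol_to_lonlat(self, rows, cols):
        lon = self.lon_min + (np.asarray(cols) + 0.5) * self.cell_width_deg
        lat = self.lat_max - (np.asarray(rows) + 0.5) * self.cell_height_deg
        return lon, lat

    def lonlat_to_rowcol(self, lon, lat):
        """Cell indices containing the given points (half-open cells)."""
        col = np.floor((np.asarray(lon) - self.lon_min) / self.cell_width_deg).astype(int)
        row = np.floor((self.lat_max - np.asarray(lat)) / self.cell_height_deg).astype(int)
        col = np.clip(col, 0, self.n_cols - 1)
        row = np.clip(row, 0, self.n_rows - 1)
        return row, col

    # -- values -------------------------------------------------------------
    @property
    def mask(self) -> np.ndarray:
        """Boolean grid, True where any band is nodata."""
        return np.isnan(self.values).any(axis=0)

    def band(self, name: str) -> np.ndarray:
        try:
            i = self.variables.index(name)
        except ValueError:
            raise KeyError(f"unknown variable {name!r}") from None
        return self.values[i]

    def extract(self, lon, lat) -> np.ndarray:
        """Environmental values at points, shape (n_points, n_vars)."""
        row, col = self.lonlat_to_rowcol(lon, lat)
        return self.values[:, row, col].T

    def table(self) -> np.ndarray:
        """All non-masked cells as a (n_valid, n_vars) array."""
        ok = ~self.mask
        return self.values[:, ok].T

    def valid_rowcol(self) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(~self.mask)

    def copy(self) -> "RasterStack":
        return RasterStack(list(self.variables), self.values.copy(),
                           self.lon_min, self.lon_max, self.lat_min, self.lat_max,
                           dict(self.meta))

    # -- I/O ----------------------------------------------------------------
    def write_dir(self, path) -> None:
        """Write one ASCII grid per variable plus a stack.json sidecar."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for i, name in enumerate(self.variables):
            write_ascii_grid(path / f"{name}.asc", self.values[i],
                             self.lon_min, self.lat_min,
                             self.cell_width_deg, self.cell_height_deg)
        sidecar = {"variables": self.variables,
                   "lon_min": self.lon_min, "lon_max": self.lon_max,
                   "lat_min": self.lat_min, "lat_max": self.lat_max,
                   "meta": self.meta}
        (path / "stack.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read_dir(cls, path) -> "RasterStack":
        path = Path(path)
        sidecar = json.loads((path / "stack.json").read_text())
        bands = [read_ascii_grid(path / f"{v}.asc")[0] for v in sidecar["variables"]]
        return cls(sidecar["variables"], np.stack(bands),
                   sidecar["lon_min"], sidecar["lon_max"],
                   sidecar["lat_min"], sidecar["lat_max"],
                   sidecar.get("meta", {}))


_NODATA = -9999.0


def write_ascii_grid(path, grid, xll, yll, dx, dy) -> None:
    """Write a 2-D array as an ESRI ASCII grid (row 0 = north)."""
    grid = np.asarray(grid, dtype=float)
    out = np.where(np.isnan(grid), _NODATA, grid)
    if abs(dx - dy) <= 1e-12 * max(dx, dy):
        size = f"cellsize {float(dx)!r}\n"
    else:  # rectangular cells use the dx/dy AAIGrid extension
        size = f"dx {float(dx)!r}\ndy {float(dy)!r}\n"
    header = (f"ncols {grid.shape[1]}\nnrows {grid.shape[0]}\n"
              f"xllcorner {float(xll)!r}\nyllcorner {float(yll)!r}\n"
              + size + f"NODATA_value {_NODATA}\n")
    body = "\n".join(" ".join(f"{v:.17g}" for v in row) for row in out)
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path):
    """Read an ESRI ASCII grid; returns (array with NaN nodata, header dict)."""
    lines = Path(path).read_text().splitlines()
    header = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "dx", "dy", "nodata_value"}:
        key, val = lines[i].split()
        header[key.lower()] = float(val)
        i += 1
    grid = np.array([[float(v) for v in line.split()] for line in lines[i:] if line.strip()])
    nodata = header.get("nodata_value", _NODATA)
    grid[grid == nodata] = np.nan
    return grid, header
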