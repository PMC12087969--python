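"""Gridded climate slices and plain-text (ESRI ASCII) raster I/O.

A :class:`ClimateSlice` holds one multi-variable lon/lat grid for one time
interval (age in Ma).  Grids are equal-angle with cell-centre coordinates;
global means are cos(latitude)-weighted so a slice's stated mean annual
temperature is an area mean, not a cell mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ClimateSlice", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class ClimateSlice:
    """One time interval's gridded environment.

    ``variables`` maps variable name -> (nlat, nlon) array, row 0 = northmost
    latitude band (standard raster orientation).
    """

    age_ma: float
    lats: np.ndarray  # cell-centre latitudes, degrees, descending
    lons: np.ndarray  # cell-centre longitudes, degrees, ascending
    variables: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.lats), len(self.lons))

    def __post_init__(self):
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        for k, v in self.variables.items():
            v = np.asarray(v, dtype=float)
            if v.shape != self.shape:
                raise ValueError(f"variable {k!r} has shape {v.shape}, expected {self.shape}")
            self.variables[k] = v

    def area_weights(self) -> np.ndarray:
        w = np.cos(np.deg2rad(self.lats))
        w2 = np.repeat(w[:, None], len(self.lons), axis=1)
        return w2 / w2.sum()

    def global_mean(self, name: str) -> float:
        return float((self.variables[name] * self.area_weights()).sum())

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        i = int(np.argmin(np.abs(self.lats - lat)))
        j = int(np.argmin(np.abs(self.lons - lon)))
        return i, j

    def env_at(self, lon: float, lat: float, names=None) -> dict[str, float]:
        i, j = self.cell_of(lon, lat)
        names = list(self.variables) if names is None else names
        return {k: float(self.variables[k][i, j]) for k in names}

    def table(self, names=None) -> np.ndarray:
        """Flattened (ncell, nvar) design matrix in row-major cell order."""
        names = list(self.variables) if names is None else names
        return np.column_stack([self.variables[k].ravel() for k in names])


def write_ascii_grid(path, grid: np.ndarray, xll: float, yll: float, cellsize: float,
                     nodata: float = -9999.0) -> None:
    grid = np.asarray(grid, dtype=float)
    nrows, ncols = grid.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\nnrows {nrows}\n")
        fh.write(f"xllcorner {xll:.10g}\nyllcorner {yll:.10g}\n")
        fh.write(f"cellsize {cellsize:.10g}\nNODATA_value {nodata:.10g}\n")
        for row in grid:
            fh.write(" ".join(f"{v:.8g}" for v in row) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0][0].isalpha():
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    grid = np.array(rows, dtype=float)
    if "ncols" in header and grid.shape[1] != int(header["ncols"]):
        raise ValueError("grid width disagrees with header ncols")
    return grid, header
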