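"""Minimal single-band raster stack with plain-text (ESRI ASCII grid) I/O.

Rasters use a unit-cell geotransform: cell (row, col) has its centre at
x = col + 0.5, y = nrows - row - 0.5 (row 0 is the top of the grid), so
coordinates written to SWD tables round-trip to cell indices exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RasterStack", "read_ascii_grid", "write_ascii_grid"]

NODATA = -9999.0


@dataclass
class RasterStack:
    """Named stack of aligned 2-D grids, NaN marking missing cells."""

    names: list[str]
    grids: np.ndarray  # (n_layers, rows, cols), float, NaN = missing

    def __post_init__(self) -> None:
        self.grids = np.asarray(self.grids, dtype=float)
        if self.grids.ndim != 3:
            raise ValueError("grids must be (n_layers, rows, cols)")
        if len(self.names) != self.grids.shape[0]:
            raise ValueError("one name per layer required")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grids.shape[1:]

    @property
    def n_cells(self) -> int:
        rows, cols = self.shape
        return rows * cols

    def layer(self, name: str) -> np.ndarray:
        return self.grids[self.names.index(name)]

    def select(self, names: list[str]) -> "RasterStack":
        idx = [self.names.index(n) for n in names]
        return RasterStack(names=list(names), grids=self.grids[idx])

    def valid_mask(self) -> np.ndarray:
        """Cells with no missing value in any layer."""
        return ~np.isnan(self.grids).any(axis=0)

    def cell_coords(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        nrows = self.shape[0]
        return np.column_stack([cols + 0.5, nrows - rows - 0.5])

    def table_at(self, rows: np.ndarray, cols: np.ndarray) -> pd.DataFrame:
        """Covariate DataFrame at the given cells, one row per cell."""
        return pd.DataFrame(
            {n: self.grids[i][rows, cols] for i, n in enumerate(self.names)}
        )

    def flat_table(self) -> pd.DataFrame:
        """All cells in row-major order (including missing)."""
        return pd.DataFrame(
            {n: self.grids[i].ravel() for i, n in enumerate(self.names)}
        )

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, grid in zip(self.names, self.grids):
            write_ascii_grid(grid, directory / f"{name}.asc")

    @classmethod
    def load(cls, directory, names: list[str] | None = None) -> "RasterStack":
        directory = Path(directory)
        if names is None:
            names = sorted(p.stem for p in directory.glob("*.asc"))
        if not names:
            raise FileNotFoundError(f"no .asc layers found in {directory}")
        grids = np.stack([read_ascii_grid(directory / f"{n}.asc") for n in names])
        return cls(names=list(names), grids=grids)


def write_ascii_grid(grid: np.ndarray, path) -> None:
    grid = np.asarray(grid, dtype=float)
    rows, cols = grid.shape
    out = np.where(np.isnan(grid), NODATA, grid)
    header = (
        f"ncols {cols}\nnrows {rows}\nxllcorner 0.0\nyllcorner 0.0\n"
        f"cellsize 1.0\nNODATA_value {NODATA}\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path) -> np.ndarray:
    with open(path, "r", encoding="utf-8") as fh:
        header = {}
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, value = line.partition(" ")
            header[key.strip().lower()] = value.strip()
        nodata = float(header.get("nodata_value", NODATA))
        grid = np.loadtxt(fh)
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    grid[grid == nodata] = np.nan
    rows, cols = int(header["nrows"]), int(header["ncols"])
    if grid.shape != (rows, cols):
        raise ValueError(f"{path}: grid shape {grid.shape} != header ({rows}, {cols})")
    return grid
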