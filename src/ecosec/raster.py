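"""Categorical land-use rasters and plain-text grid I/O.

The package works on classified land-use maps: integer class codes on a
regular square grid in a projected coordinate system (meters).  Rasters are
exchanged as ESRI ASCII grids (``.asc``), a text format readable by every
mainstream GIS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["LandUseRaster", "read_ascii_grid", "write_ascii_grid"]

DEFAULT_NODATA = -9999


@dataclass
class LandUseRaster:
    """Categorical grid with cell size, origin and class legend.

    Parameters
    ----------
    data
        2-D integer array, row 0 = northernmost row (image convention).
    cell_size
        Cell edge length in meters.
    origin
        ``(x, y)`` of the lower-left corner of the grid, in meters.
    nodata
        Integer code marking cells outside the study area.
    legend
        Optional mapping of class code to class name.
    """

    data: np.ndarray
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: int = DEFAULT_NODATA
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("raster data must hold integer class codes")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size**2

    @property
    def cell_area_hm2(self) -> float:
        """Cell area in hectares (1 hm^2 = 10^4 m^2)."""
        return self.cell_size**2 / 1e4

    def class_codes(self) -> np.ndarray:
        """Sorted codes present in the raster, nodata excluded."""
        codes = np.unique(self.data)
        return codes[codes != self.nodata]

    def class_counts(self) -> dict[int, int]:
        codes, counts = np.unique(self.data, return_counts=True)
        return {int(c): int(n) for c, n in zip(codes, counts) if c != self.nodata}

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates of every cell as ``(x, y)`` 2-D arrays."""
        n_rows, n_cols = self.data.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(n_cols) + 0.5) * self.cell_size
        # row 0 is the top row
        ys = y0 + (n_rows - np.arange(n_rows) - 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def copy(self) -> "LandUseRaster":
        return LandUseRaster(
            self.data.copy(), self.cell_size, self.origin, self.nodata, dict(self.legend)
        )

    def save(self, path: str | Path) -> None:
        write_ascii_grid(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "LandUseRaster":
        return read_ascii_grid(path)


def write_ascii_grid(raster: LandUseRaster, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid (.asc)."""
    n_rows, n_cols = raster.data.shape
    header = (
        f"ncols {n_cols}\n"
        f"nrows {n_rows}\n"
        f"xllcorner {raster.origin[0]:.6f}\n"
        f"yllcorner {raster.origin[1]:.6f}\n"
        f"cellsize {raster.cell_size:.6f}\n"
        f"NODATA_value {raster.nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.data, fmt="%d")


def read_ascii_grid(path: str | Path) -> LandUseRaster:
    """Read an ESRI ASCII grid into a :class:`LandUseRaster`."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, value = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"}:
                meta[key] = float(value)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        data = np.loadtxt(fh, dtype=np.int64, ndmin=2)
    nodata = int(meta.get("nodata_value", DEFAULT_NODATA))
    raster = LandUseRaster(
        data,
        cell_size=meta.get("cellsize", 1.0),
        origin=(meta.get("xllcorner", 0.0), meta.get("yllcorner", 0.0)),
        nodata=nodata,
    )
    if data.shape != (int(meta.get("nrows", data.shape[0])), int(meta.get("ncols", data.shape[1]))):
        raise ValueError(f"grid shape {data.shape} disagrees with header in {path}")
    return raster
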