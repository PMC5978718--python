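"""Regular lat-lon climate rasters and ESRI ASCII grid I/O.

All layers of an :class:`EnvGrid` share one grid: origin at the lower-left
corner, square cells of ``cellsize`` degrees, rows stored north-up
(row 0 = northernmost) as in the ESRI ASCII convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: The climate variable set used throughout: yearly ocean salinity, surface
#: air temperature summaries, sea surface temperature summaries, and four
#: monthly precipitation layers (January, April, July, October).
CLIMATE_VARIABLES = (
    "SAL",
    "SATmax", "SATmean", "SATmin", "SATrange",
    "SSTmax", "SSTmean", "SSTmin", "SSTrange",
    "PREC-01", "PREC-04", "PREC-07", "PREC-10",
)


@dataclass
class EnvGrid:
    """A stack of co-registered lat-lon rasters, one per climate variable.

    Parameters
    ----------
    lon0, lat0 : float
        Lower-left corner of the grid (degrees).
    cellsize : float
        Cell edge length in degrees; cells are half-open
        ``[lon, lon+cellsize) x [lat, lat+cellsize)``.
    layers : dict
        Variable name -> 2-D array of shape (nrows, ncols), row 0 north.
    nodata : float
        Missing-value marker stored in the arrays.
    """

    lon0: float
    lat0: float
    cellsize: float
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.cellsize <= 0:
            raise ValueError("cellsize must be > 0")
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) > 1:
            raise ValueError(f"layers do not share one grid: shapes {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        arr = next(iter(self.layers.values()))
        return arr.shape

    @property
    def variables(self) -> list[str]:
        return list(self.layers)

    def lon_centers(self) -> np.ndarray:
        _, ncols = self.shape
        return self.lon0 + (np.arange(ncols) + 0.5) * self.cellsize

    def lat_centers(self) -> np.ndarray:
        nrows, _ = self.shape
        # row 0 is the northernmost row
        return self.lat0 + (nrows - 0.5 - np.arange(nrows)) * self.cellsize

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/col of the half-open cell containing a point; raises if outside."""
        nrows, ncols = self.shape
        col = math.floor((lon - self.lon0) / self.cellsize)
        row_from_bottom = math.floor((lat - self.lat0) / self.cellsize)
        row = nrows - 1 - row_from_bottom
        if not (0 <= col < ncols and 0 <= row < nrows):
            raise IndexError(f"point ({lon}, {lat}) outside grid")
        return row, col

    def value_at(self, variable: str, lon: float, lat: float) -> float:
        row, col = self.cell_index(lon, lat)
        return float(self.layers[variable][row, col])

    def _interpolator(self, variable: str):
        cache = self.__dict__.setdefault("_interp_cache", {})
        if variable not in cache:
            from scipy.interpolate import RegularGridInterpolator

            arr = self.layers[variable].astype(float)
            arr = np.where(arr == self.nodata, np.nan, arr)
            lats_axis = self.lat_centers()[::-1]  # ascending
            cache[variable] = RegularGridInterpolator(
                (lats_axis, self.lon_centers()), arr[::-1, :],
                method="linear", bounds_error=False, fill_value=np.nan,
            )
        return cache[variable]

    def interpolate(self, variable: str, lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
        """Bilinear interpolation of cell-center values; nodata -> NaN.

        Points beyond the outermost cell centers return NaN.
        """
        pts = np.column_stack([np.asarray(lats, float), np.asarray(lons, float)])
        return self._interpolator(variable)(pts)


def write_ascii_grid(path: str | Path, grid: EnvGrid, variable: str) -> None:
    """Write one layer as an ESRI ASCII grid (.asc)."""
    arr = grid.layers[variable]
    nrows, ncols = arr.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {float(grid.lon0)!r}\n"
        f"yllcorner {float(grid.lat0)!r}\n"
        f"cellsize {float(grid.cellsize)!r}\n"
        f"NODATA_value {float(grid.nodata)!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, arr, fmt="%.6g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, float, float, float]:
    """Read one ESRI ASCII grid; returns (array, lon0, lat0, cellsize, nodata)."""
    head: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            head[key.lower()] = float(val)
        arr = np.loadtxt(fh)
    arr = np.atleast_2d(arr)
    if arr.shape != (int(head["nrows"]), int(head["ncols"])):
        raise ValueError(f"grid shape {arr.shape} does not match header in {path}")
    cell = head["cellsize"]
    lon0 = head.get("xllcorner", head.get("xllcenter", 0.0) - cell / 2)
    lat0 = head.get("yllcorner", head.get("yllcenter", 0.0) - cell / 2)
    return arr, lon0, lat0, cell, head.get("nodata_value", -9999.0)


def read_env_dir(path: str | Path, nodata: float | None = None) -> EnvGrid:
    """Load every ``*.asc`` in a directory as one EnvGrid (filename = variable)."""
    path = Path(path)
    files = sorted(path.glob("*.asc"))
    if not files:
        raise FileNotFoundError(f"no .asc rasters in {path}")
    layers = {}
    meta = None
    for f in files:
        arr, lon0, lat0, cell, nd = read_ascii_grid(f)
        if meta is None:
            meta = (lon0, lat0, cell, nd)
        elif (lon0, lat0, cell) != meta[:3]:
            raise ValueError(f"{f.name} is not co-registered with the other layers")
        layers[f.stem] = arr
    lon0, lat0, cell, nd = meta
    return EnvGrid(lon0, lat0, cell, layers, nodata if nodata is not None else nd)


def write_env_dir(path: str | Path, grid: EnvGrid) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for var in grid.variables:
        write_ascii_grid(path / f"{var}.asc", grid, var)
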