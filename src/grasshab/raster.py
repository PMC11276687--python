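"""Grid/raster containers and GeoTIFF I/O.

Raster convention used throughout the package: row 0 is the northern-most
row, registration is cell-center, and all coordinates refer to cell centers.
Grids are either local planar (cell size in km) or geographic (cell size in
decimal degrees); the distinction only matters for area accounting.

GeoTIFF files are written through :mod:`tifffile` with the standard geo
tags (ModelPixelScale, ModelTiepoint and GDAL_NODATA), single band per
layer, float32 for continuous data and int16 for categorical data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "GridSpec",
    "Raster",
    "EnvStack",
    "read_geotiff",
    "write_geotiff",
    "KM_PER_DEGREE",
]

# Mean great-circle kilometres per degree of latitude (spherical Earth).
KM_PER_DEGREE = 111.19493

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

_CONTINUOUS_NODATA = -9999.0
_CATEGORICAL_NODATA = -9999


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up, cell-center registered raster grid.

    Parameters
    ----------
    nrows, ncols
        Grid shape; row 0 is the northern-most row.
    xmin, ymax
        Coordinates of the *outer corner* of the top-left cell.
    cell
        Square cell size (km for planar grids, degrees for geographic).
    geographic
        If True coordinates are lon/lat degrees and cell areas carry a
        cosine-latitude correction; otherwise the grid is local planar
        with ``cell`` in kilometres.
    """

    nrows: int
    ncols: int
    xmin: float
    ymax: float
    cell: float
    geographic: bool = False

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def xmax(self) -> float:
        return self.xmin + self.ncols * self.cell

    @property
    def ymin(self) -> float:
        return self.ymax - self.nrows * self.cell

    def x_centers(self) -> np.ndarray:
        return self.xmin + (np.arange(self.ncols) + 0.5) * self.cell

    def y_centers(self) -> np.ndarray:
        return self.ymax - (np.arange(self.nrows) + 0.5) * self.cell

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.xmin + (col + 0.5) * self.cell,
            self.ymax - (row + 0.5) * self.cell,
        )

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing point (x, y); may be out of range."""
        col = int(math.floor((x - self.xmin) / self.cell))
        row = int(math.floor((self.ymax - y) / self.cell))
        return row, col

    def contains(self, x: float, y: float) -> bool:
        row, col = self.index_of(x, y)
        return 0 <= row < self.nrows and 0 <= col < self.ncols

    def cell_areas_km2(self) -> np.ndarray:
        """Per-row cell area in km² (length nrows).

        Planar grids: cell²; geographic grids: per-row cosine-latitude
        corrected spherical quadrangle approximation.
        """
        if not self.geographic:
            return np.full(self.nrows, self.cell**2)
        lat = self.y_centers()
        return (KM_PER_DEGREE * self.cell) ** 2 * np.cos(np.radians(lat))


class Raster:
    """A single-band raster: float64 data with NaN as nodata, plus a grid."""

    def __init__(self, data: np.ndarray, grid: GridSpec, categorical: bool = False):
        data = np.asarray(data, dtype=float)
        if data.shape != grid.shape:
            raise ValueError(
                f"data shape {data.shape} does not match grid {grid.shape}"
            )
        self.data = data
        self.grid = grid
        self.categorical = bool(categorical)

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        return ~np.isnan(self.data)

    def copy(self) -> "Raster":
        return Raster(self.data.copy(), self.grid, self.categorical)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "categorical" if self.categorical else "continuous"
        return f"Raster({self.grid.nrows}x{self.grid.ncols}, {kind})"


class EnvStack:
    """An aligned stack of named environmental layers on one grid.

    The stack keeps a union nodata mask: a cell is valid only if every
    layer has data there. Layers are tagged continuous or categorical;
    categorical layers hold small integer level codes.
    """

    def __init__(self, grid: GridSpec):
        self.grid = grid
        self._layers: dict[str, np.ndarray] = {}
        self._kinds: dict[str, str] = {}

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    @property
    def continuous_names(self) -> list[str]:
        return [n for n, k in self._kinds.items() if k == "continuous"]

    @property
    def categorical_names(self) -> list[str]:
        return [n for n, k in self._kinds.items() if k == "categorical"]

    def kind(self, name: str) -> str:
        return self._kinds[name]

    def add(self, name: str, data: np.ndarray, kind: str = "continuous") -> None:
        if kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown layer kind {kind!r}")
        data = np.asarray(data, dtype=float)
        if data.shape != self.grid.shape:
            raise ValueError(
                f"layer {name!r} shape {data.shape} != grid {self.grid.shape}"
            )
        if name in self._layers:
            raise ValueError(f"duplicate layer name {name!r}")
        self._layers[name] = data
        self._kinds[name] = kind

    def layer(self, name: str) -> np.ndarray:
        return self._layers[name]

    def raster(self, name: str) -> Raster:
        return Raster(
            self._layers[name], self.grid, self._kinds[name] == "categorical"
        )

    @property
    def valid_mask(self) -> np.ndarray:
        """Union-of-nodata mask: True where every layer has data."""
        mask = np.ones(self.grid.shape, dtype=bool)
        for data in self._layers.values():
            mask &= ~np.isnan(data)
        return mask

    def valid_indices(self) -> np.ndarray:
        """(n, 2) array of [row, col] for valid cells, row-major order."""
        return np.argwhere(self.valid_mask)

    def table(self, rows: np.ndarray, cols: np.ndarray) -> dict[str, np.ndarray]:
        """Covariate values at the given cell indices, one vector per layer."""
        return {n: d[rows, cols] for n, d in self._layers.items()}

    def __len__(self) -> int:
        return len(self._layers)

    def __contains__(self, name: str) -> bool:
        return name in self._layers


def write_geotiff(path: str | Path, raster: Raster) -> None:
    """Write a single-band GeoTIFF (float32 continuous / int16 categorical)."""
    path = Path(path)
    g = raster.grid
    if raster.categorical:
        data = raster.data.copy()
        data[np.isnan(data)] = _CATEGORICAL_NODATA
        arr = data.astype(np.int16)
        nodata = _CATEGORICAL_NODATA
    else:
        data = raster.data.copy()
        data[np.isnan(data)] = _CONTINUOUS_NODATA
        arr = data.astype(np.float32)
        nodata = _CONTINUOUS_NODATA
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (g.cell, g.cell, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.xmin, g.ymax, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    description = "geographic" if g.geographic else "planar-km"
    try:
        tifffile.imwrite(
            path, arr, extratags=extratags, description=description
        )
    except OSError as exc:  # pragma: no cover - exercised via error path test
        raise OSError(f"failed to write raster {path}: {exc}") from exc


def read_geotiff(path: str | Path) -> Raster:
    """Read a single-band GeoTIFF written by :func:`write_geotiff` (or any
    GeoTIFF carrying ModelPixelScale + ModelTiepoint tags)."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        tags = page.tags
        try:
            scale = tags[_TAG_MODEL_PIXEL_SCALE].value
            tiepoint = tags[_TAG_MODEL_TIEPOINT].value
        except KeyError as exc:
            raise ValueError(f"{path} lacks GeoTIFF georeferencing tags") from exc
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        description = ""
        if 270 in tags:  # ImageDescription
            description = str(tags[270].value)
    if arr.ndim != 2:
        raise ValueError(f"{path} is not single-band")
    cell = float(scale[0])
    # Tiepoint maps raster (0,0) corner to model (x, y).
    xmin = float(tiepoint[3])
    ymax = float(tiepoint[4])
    categorical = np.issubdtype(arr.dtype, np.integer)
    data = arr.astype(float)
    if nodata is not None:
        data[arr == nodata] = np.nan
    grid = GridSpec(
        nrows=arr.shape[0],
        ncols=arr.shape[1],
        xmin=xmin,
        ymax=ymax,
        cell=cell,
        geographic=description.strip() == "geographic",
    )
    return Raster(data, grid, categorical=categorical)
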