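"""Analysis-ready covariate preparation.

Covers the standard remote-sensing/meteorology preprocessing chain:
fractional vegetation cover from NDVI via the dimidiate pixel model,
maximum-value compositing of thermal time series, ordinary-kriging
interpolation of station observations onto the analysis grid, and
resampling of heterogeneous layers onto one common grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial.distance import cdist

from .raster import EnvStack, GridSpec, Raster

__all__ = [
    "FvcParams",
    "StationSet",
    "VariogramSpec",
    "compute_fvc",
    "max_composite",
    "interpolate_stations",
    "align_stack",
    "slope_aspect",
]


@dataclass(frozen=True)
class FvcParams:
    """Dimidiate-pixel endmembers: NDVI of pure soil and pure vegetation."""

    ndvi0: float  # pure soil
    ndviv: float  # pure vegetation

    def __post_init__(self) -> None:
        if not self.ndviv > self.ndvi0:
            raise ValueError(
                f"degenerate endmembers: NDVIv ({self.ndviv}) must exceed "
                f"NDVI0 ({self.ndvi0})"
            )

    @classmethod
    def from_percentiles(cls, ndvi: Raster, lo: float = 5.0, hi: float = 95.0
                         ) -> "FvcParams":
        """Dark/bright endmember heuristic: NDVI percentiles over valid cells."""
        vals = ndvi.data[ndvi.mask]
        if vals.size == 0:
            raise ValueError("NDVI raster has no valid cells")
        return cls(ndvi0=float(np.percentile(vals, lo)),
                   ndviv=float(np.percentile(vals, hi)))


def compute_fvc(ndvi: Raster, params: FvcParams) -> Raster:
    """FVC = (NDVI - NDVI0) / (NDVIv - NDVI0), clipped to [0, 1].

    Values beyond the pure endmembers are clipped rather than masked, so
    output pixels lie in [0, 1]; nodata propagates unchanged.
    """
    fvc = (ndvi.data - params.ndvi0) / (params.ndviv - params.ndvi0)
    fvc = np.clip(fvc, 0.0, 1.0)
    fvc[~ndvi.mask] = np.nan
    return Raster(fvc, ndvi.grid)


def max_composite(series: list[Raster]) -> Raster:
    """Per-cell maximum over a raster series, skipping nodata.

    A cell is nodata in the composite only when it is nodata in every
    input. All rasters must share one grid.
    """
    if not series:
        raise ValueError("empty raster series")
    grid = series[0].grid
    for r in series[1:]:
        if r.grid != grid:
            raise ValueError("raster series is not on a common grid")
    cube = np.stack([r.data for r in series])
    all_nan = np.all(np.isnan(cube), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmax(cube, axis=0)
    out[all_nan] = np.nan
    return Raster(out, grid)


class StationSet:
    """Point observations of one meteorological variable."""

    def __init__(self, x: np.ndarray, y: np.ndarray, value: np.ndarray):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        value = np.asarray(value, dtype=float)
        if not (len(x) == len(y) == len(value)):
            raise ValueError("x, y, value must have equal length")
        if len(x) < 3:
            raise ValueError("kriging needs at least 3 stations")
        coords = np.column_stack([x, y])
        if len(np.unique(coords, axis=0)) != len(coords):
            raise ValueError("duplicate station coordinates")
        self.x, self.y, self.value = x, y, value

    def __len__(self) -> int:
        return len(self.x)

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass(frozen=True)
class VariogramSpec:
    """Semivariogram model: gamma(h) = nugget + (sill-nugget) * g(h/range).

    ``model`` is exponential (practical-range form, 1 - exp(-3h/a)),
    spherical, or gaussian. Defaults when fields are None: range = one
    third of the domain diagonal, sill = sample variance, nugget = 0.
    """

    model: str = "exponential"
    range_: float | None = None
    sill: float | None = None
    nugget: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in ("exponential", "spherical", "gaussian"):
            raise ValueError(f"unknown variogram model {self.model!r}")
        if self.nugget < 0:
            raise ValueError("nugget must be non-negative")

    def resolved(self, stations: StationSet, grid: GridSpec) -> "VariogramSpec":
        rng = self.range_
        if rng is None:
            diag = float(np.hypot(grid.xmax - grid.xmin, grid.ymax - grid.ymin))
            rng = diag / 3.0
        sill = self.sill
        if sill is None:
            sill = float(np.var(stations.value))
            if sill == 0.0:
                sill = 1.0  # constant field; any positive sill gives weights
        return VariogramSpec(self.model, rng, sill, self.nugget)

    def gamma(self, h: np.ndarray) -> np.ndarray:
        a = self.range_
        c = self.sill - self.nugget
        h = np.asarray(h, dtype=float)
        if self.model == "exponential":
            g = 1.0 - np.exp(-3.0 * h / a)
        elif self.model == "gaussian":
            g = 1.0 - np.exp(-3.0 * (h / a) ** 2)
        else:  # spherical
            hr = np.clip(h / a, 0.0, 1.0)
            g = 1.5 * hr - 0.5 * hr**3
        out = self.nugget + c * g
        return np.where(h == 0.0, 0.0, out)


def interpolate_stations(stations: StationSet, grid: GridSpec,
                         variogram: VariogramSpec | None = None) -> Raster:
    """Ordinary kriging of station values onto every grid cell center.

    The Lagrange-multiplier system enforces weights summing to 1 at each
    prediction point; with a zero nugget the surface interpolates the
    stations exactly.

    Raises
    ------
    np.linalg.LinAlgError
        Wrapped with a hint to add a nugget when the system is singular.
    """
    vg = (variogram or VariogramSpec()).resolved(stations, grid)
    n = len(stations)
    d_ss = cdist(stations.coords, stations.coords)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = vg.gamma(d_ss)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    A[n, n] = 0.0

    xs = grid.x_centers()
    ys = grid.y_centers()
    gx, gy = np.meshgrid(xs, ys)
    targets = np.column_stack([gx.ravel(), gy.ravel()])
    B = np.empty((n + 1, len(targets)))
    B[:n] = vg.gamma(cdist(stations.coords, targets))
    B[n] = 1.0
    try:
        lam = np.linalg.solve(A, B)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular kriging system; try a nugget > 0"
        ) from exc
    pred = stations.value @ lam[:n]
    return Raster(pred.reshape(grid.shape), grid)


def kriging_weights(stations: StationSet, grid: GridSpec,
                    variogram: VariogramSpec | None = None) -> np.ndarray:
    """Ordinary-kriging weight matrix (n_stations, n_cells); columns sum to 1."""
    vg = (variogram or VariogramSpec()).resolved(stations, grid)
    n = len(stations)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = vg.gamma(cdist(stations.coords, stations.coords))
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    A[n, n] = 0.0
    gx, gy = np.meshgrid(grid.x_centers(), grid.y_centers())
    targets = np.column_stack([gx.ravel(), gy.ravel()])
    B = np.empty((n + 1, len(targets)))
    B[:n] = vg.gamma(cdist(stations.coords, targets))
    B[n] = 1.0
    lam = np.linalg.solve(A, B)
    return lam[:n]


def _resample(raster: Raster, target: GridSpec, order: int) -> np.ndarray:
    """Resample onto target cell centers; order 0 = nearest, 1 = bilinear."""
    src = raster.grid
    # Fractional source array indices of target cell centers.
    tx = target.x_centers()
    ty = target.y_centers()
    cols = (tx - src.xmin) / src.cell - 0.5
    rows = (src.ymax - ty) / src.cell - 0.5
    cgrid, rgrid = np.meshgrid(cols, rows)
    inside = (
        (cgrid > -0.5) & (cgrid < src.ncols - 0.5)
        & (rgrid > -0.5) & (rgrid < src.nrows - 0.5)
    )
    if not inside.any():
        raise ValueError("no overlap between layer extent and target grid")
    data = raster.data
    nan_mask = np.isnan(data)
    filled = np.where(nan_mask, 0.0, data)
    out = map_coordinates(filled, [rgrid, cgrid], order=order,
                          mode="nearest", cval=np.nan)
    # A target cell is nodata if any contributing source cell is nodata.
    bad = map_coordinates(nan_mask.astype(float), [rgrid, cgrid],
                          order=order, mode="nearest")
    out[(bad > 1e-12) | ~inside] = np.nan
    return out


def align_stack(layers: list[tuple[str, Raster]], target: GridSpec) -> EnvStack:
    """Resample tagged layers onto a common target grid.

    Continuous layers are resampled bilinearly; categorical layers by
    nearest neighbour (so no new level values can appear). The stack's
    valid mask is the union-of-nodata across layers.
    """
    stack = EnvStack(target)
    for name, raster in layers:
        order = 0 if raster.categorical else 1
        data = _resample(raster, target, order)
        stack.add(name, data,
                  "categorical" if raster.categorical else "continuous")
    return stack


def slope_aspect(dem: Raster) -> tuple[Raster, Raster]:
    """Slope (degrees) and aspect (degrees clockwise from north) from a DEM
    using the standard 3x3 Horn stencil. Cells touching nodata become nodata."""
    z = dem.data
    cell = dem.grid.cell
    pad = np.pad(z, 1, mode="edge")
    # Horn neighbourhood: a b c / d e f / g h i (row 0 = north).
    a = pad[:-2, :-2]; b = pad[:-2, 1:-1]; c = pad[:-2, 2:]
    d = pad[1:-1, :-2]; f = pad[1:-1, 2:]
    g = pad[2:, :-2]; h = pad[2:, 1:-1]; i = pad[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * cell)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8.0 * cell)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    aspect = np.degrees(np.arctan2(dzdx, -dzdy)) % 360.0
    bad = np.isnan(pad[:-2, :-2]) | np.isnan(pad[:-2, 1:-1]) | np.isnan(pad[:-2, 2:]) \
        | np.isnan(pad[1:-1, :-2]) | np.isnan(pad[1:-1, 1:-1]) | np.isnan(pad[1:-1, 2:]) \
        | np.isnan(pad[2:, :-2]) | np.isnan(pad[2:, 1:-1]) | np.isnan(pad[2:, 2:])
    slope[bad] = np.nan
    aspect[bad] = np.nan
    return Raster(slope, dem.grid), Raster(aspect, dem.grid)
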