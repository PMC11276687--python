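"""Synthetic environmental stacks, ground-truth responses and occurrences.

The generator emulates the statistical structure a grassland pest
suitability analysis assumes: spatially smooth continuous covariates
(surface temperature, vegetation cover, precipitation, elevation) with
controlled pairwise correlation, categorical layers (vegetation type,
soil type) formed as contiguous regions, and presence points marked
where a simulated insect density exceeds an outbreak threshold
(default 15 individuals per m², the survey convention for marking a
quadrat as a distribution point).

Smooth fields are seeded white noise convolved with a Gaussian kernel
and rank-mapped to target marginal ranges. Correlated pairs are built
by mixing independent Gaussian fields with analytically derived
weights; because rank-mapping sends Gaussian marginals to uniform ones,
the mixing correlation is pre-adjusted (r_gauss = 2 sin(pi r / 6)) so
the *post-mapping* Pearson correlation hits the requested target.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .raster import EnvStack, GridSpec, Raster, write_geotiff

__all__ = [
    "ResponseTerm",
    "TrueResponseModel",
    "SimConfig",
    "generate_env_stack",
    "sample_occurrences",
    "write_fixture",
    "default_truth",
    "strong_signal_truth",
    "OccurrenceSet",
]


@dataclass(frozen=True)
class ResponseTerm:
    """One additive term of the true response surface.

    ``shape`` is one of ``linear``, ``quadratic``, ``hinge`` or
    ``categorical``. Continuous terms act on the variable scaled to
    [0, 1] by its min/max over valid cells; a hinge term additionally
    takes a ``knot`` in (0, 1) and evaluates max(0, (z - knot)/(1 - knot)).
    A categorical term adds its coefficient where the layer equals
    ``level``.
    """

    variable: str
    shape: str
    coefficient: float
    knot: float | None = None
    level: int | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("linear", "quadratic", "hinge", "categorical"):
            raise ValueError(f"unknown term shape {self.shape!r}")
        if self.shape == "hinge" and not (self.knot is not None and 0 < self.knot < 1):
            raise ValueError("hinge term requires a knot in (0, 1)")
        if self.shape == "categorical" and self.level is None:
            raise ValueError("categorical term requires a level")


@dataclass(frozen=True)
class TrueResponseModel:
    """Known generative response: linear predictor -> suitability in [0, 1]."""

    terms: tuple[ResponseTerm, ...]
    intercept: float = 0.0
    link: str = "logistic"

    def __post_init__(self) -> None:
        if self.link not in ("logistic", "clip"):
            raise ValueError(f"unknown link {self.link!r}")

    @property
    def variables(self) -> list[str]:
        seen: list[str] = []
        for t in self.terms:
            if t.variable not in seen:
                seen.append(t.variable)
        return seen

    def suitability(self, stack: EnvStack) -> np.ndarray:
        """Suitability surface in [0, 1]; NaN outside the valid mask."""
        missing = [v for v in self.variables if v not in stack]
        if missing:
            raise ValueError(f"truth references unknown variables: {missing}")
        valid = stack.valid_mask
        eta = np.full(stack.grid.shape, float(self.intercept))
        for t in self.terms:
            data = stack.layer(t.variable)
            if t.shape == "categorical":
                eta += t.coefficient * (data == t.level)
                continue
            lo = np.nanmin(data[valid])
            hi = np.nanmax(data[valid])
            z = (data - lo) / (hi - lo) if hi > lo else np.zeros_like(data)
            if t.shape == "linear":
                eta += t.coefficient * z
            elif t.shape == "quadratic":
                eta += t.coefficient * z**2
            else:  # hinge
                eta += t.coefficient * np.maximum(0.0, (z - t.knot) / (1 - t.knot))
        if self.link == "logistic":
            suit = 1.0 / (1.0 + np.exp(-eta))
        else:
            suit = np.clip(eta, 0.0, 1.0)
        suit = np.where(valid, suit, np.nan)
        return suit

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "link": self.link,
            "terms": [
                {
                    "variable": t.variable,
                    "shape": t.shape,
                    "coefficient": t.coefficient,
                    **({"knot": t.knot} if t.knot is not None else {}),
                    **({"level": t.level} if t.level is not None else {}),
                }
                for t in self.terms
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrueResponseModel":
        terms = tuple(
            ResponseTerm(
                variable=t["variable"],
                shape=t["shape"],
                coefficient=float(t["coefficient"]),
                knot=t.get("knot"),
                level=t.get("level"),
            )
            for t in d["terms"]
        )
        return cls(terms=terms, intercept=float(d.get("intercept", 0.0)),
                   link=d.get("link", "logistic"))


def default_truth() -> TrueResponseModel:
    """Default ground truth: vegetation cover and soil type drive presence.

    Mirrors the field expectation that a vegetation-related variable and
    soil type dominate habitat suitability for grassland grasshoppers.
    """
    return TrueResponseModel(
        terms=(
            ResponseTerm("fvc", "hinge", 5.0, knot=0.35),
            ResponseTerm("soil", "categorical", 1.8, level=2),
            ResponseTerm("soil", "categorical", 1.2, level=3),
            ResponseTerm("soil", "categorical", -1.5, level=5),
        ),
        intercept=-3.2,
        link="logistic",
    )


def strong_signal_truth() -> TrueResponseModel:
    """Strong-signal ground truth for parameter-recovery experiments.

    Suitable habitat is rare and sharply contrasted: a steep vegetation
    hinge and large soil-type effects concentrate presences so a
    competent model separates them cleanly from background, while both
    drivers remain co-dominant in importance terms.
    """
    return TrueResponseModel(
        terms=(
            ResponseTerm("fvc", "hinge", 6.0, knot=0.45),
            ResponseTerm("soil", "categorical", 2.8, level=2),
            ResponseTerm("soil", "categorical", 2.0, level=3),
            ResponseTerm("soil", "categorical", -3.0, level=5),
        ),
        intercept=-5.2,
        link="logistic",
    )


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic landscape.

    Defaults emulate a 1-km grid over a typical-steppe study region at
    reduced extent: five continuous covariates with realistic marginal
    ranges, one strongly correlated temperature pair, two categorical
    layers, and an occurrence sample marked by the 15 per-m² outbreak
    density threshold.
    """

    nrows: int = 80
    ncols: int = 80
    cell: float = 1.0  # km
    geographic: bool = False
    continuous: dict = field(default_factory=lambda: {
        "lst": (-10.0, 40.0),     # land surface temperature, deg C
        "fvc": (0.0, 1.0),        # fractional vegetation cover
        "precip": (0.0, 120.0),   # monthly precipitation, mm
        "temp": (-15.0, 25.0),    # monthly mean air temperature, deg C
        "dem": (900.0, 1600.0),   # elevation, m
    })
    corr_targets: dict = field(default_factory=lambda: {("temp", "lst"): 0.85})
    categorical: dict = field(default_factory=lambda: {"veg": 5, "soil": 6})
    length_scale: float = 6.0          # Gaussian kernel sigma, cells
    n_occurrences: int = 200
    density_threshold: float = 15.0    # insects per m^2 marking presence
    max_density: float = 60.0          # density at suitability 1, per m^2
    noise_sigma: float = 0.3           # log-normal multiplicative noise sd
    border_fraction: float = 0.05      # nodata border on each edge
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nrows < 4 or self.ncols < 4:
            raise ValueError("grid too small")
        for pair, r in self.corr_targets.items():
            if not -1 < r < 1:
                raise ValueError(f"correlation target for {pair} must be in (-1, 1)")
            for v in pair:
                if v not in self.continuous:
                    raise ValueError(f"correlation pair names unknown layer {v!r}")
        if not 0 <= self.border_fraction < 0.5:
            raise ValueError("border_fraction must be in [0, 0.5)")
        if self.n_occurrences < 1:
            raise ValueError("need at least one occurrence")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.nrows, self.ncols, xmin=0.0,
                        ymax=self.nrows * self.cell, cell=self.cell,
                        geographic=self.geographic)


@dataclass(frozen=True)
class OccurrenceSet:
    """Presence coordinates with their simulated density provenance."""

    x: np.ndarray
    y: np.ndarray
    density: np.ndarray
    rows: np.ndarray
    cols: np.ndarray

    def __len__(self) -> int:
        return len(self.x)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": np.arange(len(self.x)),
            "lon": self.x,
            "lat": self.y,
            "density": self.density,
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, grid: GridSpec | None = None
                       ) -> "OccurrenceSet":
        x = df["lon"].to_numpy(dtype=float)
        y = df["lat"].to_numpy(dtype=float)
        dens = (df["density"].to_numpy(dtype=float)
                if "density" in df else np.full(len(x), np.nan))
        if grid is not None and len(x):
            rc = np.array([grid.index_of(xi, yi) for xi, yi in zip(x, y)])
            rows, cols = rc[:, 0], rc[:, 1]
        else:
            rows = np.full(len(x), -1, dtype=int)
            cols = np.full(len(x), -1, dtype=int)
        return cls(x=x, y=y, density=dens, rows=rows, cols=cols)


def _smooth_standard_field(shape: tuple[int, int], sigma: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Unit-variance spatially smooth Gaussian field."""
    white = rng.standard_normal(shape)
    f = gaussian_filter(white, sigma=sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def _rank_map(field_: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Rank-map a field to a uniform marginal on [lo, hi]."""
    flat = field_.ravel()
    order = np.argsort(flat, kind="stable")
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = np.arange(len(flat))
    u = (ranks + 0.5) / len(flat)
    return (lo + (hi - lo) * u).reshape(field_.shape)


def _gaussian_corr_matrix(names: list[str], targets: dict) -> np.ndarray:
    """Gaussian-scale correlation matrix whose rank-mapped fields attain
    the requested (post-uniform) Pearson targets."""
    k = len(names)
    idx = {n: i for i, n in enumerate(names)}
    C = np.eye(k)
    for (a, b), r in targets.items():
        rg = 2.0 * np.sin(np.pi * r / 6.0)  # uniform -> Gaussian adjustment
        C[idx[a], idx[b]] = C[idx[b], idx[a]] = rg
    return C


def generate_env_stack(cfg: SimConfig) -> EnvStack:
    """Generate an aligned stack of smooth continuous and categorical layers.

    Raises
    ------
    ValueError
        If the requested correlation structure is not positive definite;
        the message names the most demanding pair.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.grid
    names = list(cfg.continuous)
    C = _gaussian_corr_matrix(names, cfg.corr_targets)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        worst = max(cfg.corr_targets.items(), key=lambda kv: abs(kv[1]))[0]
        raise ValueError(
            "correlation targets do not form a positive-definite structure; "
            f"offending pair includes {worst}"
        ) from None
    base = np.stack([
        _smooth_standard_field(grid.shape, cfg.length_scale, rng)
        for _ in names
    ])
    mixed = np.einsum("ij,jrc->irc", L, base)

    stack = EnvStack(grid)
    border_r = int(round(cfg.border_fraction * grid.nrows))
    border_c = int(round(cfg.border_fraction * grid.ncols))
    nodata = np.zeros(grid.shape, dtype=bool)
    if border_r:
        nodata[:border_r, :] = nodata[-border_r:, :] = True
    if border_c:
        nodata[:, :border_c] = nodata[:, -border_c:] = True

    for i, name in enumerate(names):
        lo, hi = cfg.continuous[name]
        data = _rank_map(mixed[i], lo, hi)
        data[nodata] = np.nan
        stack.add(name, data, "continuous")

    for name, n_levels in cfg.categorical.items():
        latent = _smooth_standard_field(grid.shape, cfg.length_scale, rng)
        edges = np.quantile(latent, np.linspace(0, 1, n_levels + 1)[1:-1])
        levels = np.digitize(latent, edges) + 1.0  # levels 1..n
        levels[nodata] = np.nan
        stack.add(name, levels, "categorical")
    return stack


def sample_occurrences(stack: EnvStack, truth: TrueResponseModel,
                       cfg: SimConfig) -> OccurrenceSet:
    """Draw presence points where simulated density exceeds the threshold.

    Density per cell is suitability x max_density x mean-one log-normal
    noise; cells whose density exceeds ``cfg.density_threshold`` form the
    presence pool and ``cfg.n_occurrences`` cells are drawn from it
    without replacement.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    suit = truth.suitability(stack)
    valid = stack.valid_mask
    noise = rng.lognormal(mean=-cfg.noise_sigma**2 / 2.0,
                          sigma=cfg.noise_sigma, size=suit.shape)
    density = suit * cfg.max_density * noise
    pool = np.argwhere(valid & (density > cfg.density_threshold))
    if len(pool) < cfg.n_occurrences:
        raise ValueError(
            f"presence pool has only {len(pool)} cells above the density "
            f"threshold; {cfg.n_occurrences} occurrences requested"
        )
    take = rng.choice(len(pool), size=cfg.n_occurrences, replace=False)
    rows, cols = pool[take, 0], pool[take, 1]
    xy = np.array([stack.grid.cell_center(r, c) for r, c in zip(rows, cols)])
    return OccurrenceSet(
        x=xy[:, 0], y=xy[:, 1], density=density[rows, cols],
        rows=rows, cols=cols,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture(stack: EnvStack, occ: OccurrenceSet,
                  truth: TrueResponseModel, out_dir: str | Path) -> dict:
    """Write the fixture to disk: one GeoTIFF per layer, an occurrence CSV
    (``id,lon,lat,density``), the truth as YAML, and a manifest with
    checksums. Returns the manifest (also written as manifest.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, dict] = {}
    for name in stack.names:
        p = out / f"{name}.tif"
        write_geotiff(p, stack.raster(name))
        files[p.name] = {"kind": stack.kind(name), "sha256": _sha256(p)}
    occ_path = out / "occurrences.csv"
    occ.to_dataframe().to_csv(occ_path, index=False)
    files[occ_path.name] = {"kind": "occurrences", "sha256": _sha256(occ_path)}
    truth_path = out / "truth.yml"
    truth_path.write_text(yaml.safe_dump(truth.to_dict(), sort_keys=True))
    files[truth_path.name] = {"kind": "truth", "sha256": _sha256(truth_path)}
    manifest = {"files": files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
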