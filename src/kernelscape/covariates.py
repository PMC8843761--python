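"""Multiscale covariate construction.

Builds the habitat-model predictor vocabulary on a common 250-m grid:

* terrain derivatives from a DEM (slope, TRASP-transformed aspect, terrain
  ruggedness, topographic slope position),
* focal means of continuous layers within circular windows,
* FRAGSTATS-style moving-window landscape metrics on a categorical
  land-cover map (PLAND, LPI, PD, ED, SHDI, AI),
* Euclidean distance and moving-window density layers for point and line
  features (villages, roads).

Windows are circular (cell centers within the radius), truncated at raster
edges, with metrics computed over valid cells only — the moving-window
convention of FRAGSTATS.  Patch connectivity is 8-neighbor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from scipy.spatial import cKDTree

from .raster import RasterGrid

__all__ = [
    "CovariateStack",
    "WindowMetricSpec",
    "terrain_derivatives",
    "trasp",
    "focal_mean",
    "window_metric",
    "distance_to_features",
    "feature_density",
    "build_multiscale_stack",
    "STANDARD_SCALES",
]

STANDARD_SCALES = (1000, 2000, 3000, 4000, 5000, 6000)

_EIGHT = np.ones((3, 3), dtype=int)  # 8-neighbor structuring element


# ----------------------------------------------------------------------
# terrain derivatives
# ----------------------------------------------------------------------
def trasp(aspect_deg: np.ndarray) -> np.ndarray:
    """Transform compass aspect (degrees) to the 0–1 solar-radiation index.

    ``(1 - cos((pi/180)(aspect - 30))) / 2`` — 0 on north-northeast (30°)
    slopes, 1 on the opposing south-southwest (210°) slopes.
    """
    return (1.0 - np.cos(np.deg2rad(np.asarray(aspect_deg) - 30.0))) / 2.0


def terrain_derivatives(dem: RasterGrid, tpi_radius: float = 500.0):
    """Slope, TRASP aspect, terrain ruggedness and slope position from a DEM.

    Parameters
    ----------
    dem : RasterGrid
        Elevation in meters on square cells.
    tpi_radius : float
        Radius (m) of the neighborhood used for the slope-position index
        (elevation minus focal-mean elevation).

    Returns
    -------
    slope, aspect_trasp, tri, slope_position : RasterGrid
        Slope in degrees (3x3 Horn gradient); TRASP in [0, 1] (0.5 on flat
        cells where aspect is undefined); TRI as the mean absolute elevation
        difference to the 8 neighbors; slope position as elevation minus the
        focal-mean elevation within ``tpi_radius``.
    """
    if dem.nrows < 3 or dem.ncols < 3:
        raise ValueError("DEM must be at least 3x3 cells")
    z = dem.values
    cs = dem.cell_size
    zp = np.pad(z, 1, mode="edge")

    a = zp[:-2, :-2]; b = zp[:-2, 1:-1]; c = zp[:-2, 2:]
    d = zp[1:-1, :-2];                   f = zp[1:-1, 2:]
    g = zp[2:, :-2];  h = zp[2:, 1:-1];  i = zp[2:, 2:]

    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * cs)   # east +
    dzdy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8.0 * cs)   # north +

    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))

    # azimuth of the downslope vector (-dzdx, -dzdy), clockwise from north
    with np.errstate(invalid="ignore"):
        aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    asp = trasp(aspect)
    asp = np.where(slope == 0, 0.5, asp)  # aspect undefined on flat cells

    diffs = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            diffs.append(np.abs(np.roll(np.roll(zp, dr, 0), dc, 1) - zp))
    tri = np.mean(diffs, axis=0)[1:-1, 1:-1]
    # edge cells: recompute with only in-bounds neighbors
    tri_edge = _tri_truncated(z)
    edge_mask = np.zeros_like(z, dtype=bool)
    edge_mask[0, :] = edge_mask[-1, :] = True
    edge_mask[:, 0] = edge_mask[:, -1] = True
    tri = np.where(edge_mask, tri_edge, tri)

    tpi = z - focal_mean(dem, tpi_radius).values

    return (dem.like(slope), dem.like(asp), dem.like(tri), dem.like(tpi))


def _tri_truncated(z: np.ndarray) -> np.ndarray:
    nr, nc = z.shape
    out = np.zeros_like(z)
    sums = np.zeros_like(z)
    counts = np.zeros_like(z)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            r0, r1 = max(0, -dr), min(nr, nr - dr)
            c0, c1 = max(0, -dc), min(nc, nc - dc)
            sums[r0:r1, c0:c1] += np.abs(z[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
                                         - z[r0:r1, c0:c1])
            counts[r0:r1, c0:c1] += 1
    with np.errstate(invalid="ignore"):
        out = sums / counts
    return out


# ----------------------------------------------------------------------
# focal mean
# ----------------------------------------------------------------------
def circular_footprint(radius: float, cell_size: float) -> np.ndarray:
    """Boolean footprint of cells whose centers lie within ``radius``."""
    k = int(math.floor(radius / cell_size))
    offs = np.arange(-k, k + 1)
    dy, dx = np.meshgrid(offs, offs, indexing="ij")
    return (dy ** 2 + dx ** 2) * cell_size ** 2 <= radius ** 2 + 1e-9


def focal_mean(raster: RasterGrid, radius: float) -> RasterGrid:
    """Mean of values whose cell centers lie within ``radius`` of each cell.

    Nodata cells are excluded from both numerator and denominator; windows
    are truncated at the raster edge.  A radius smaller than half a cell
    returns the raster unchanged (with a warning).
    """
    if radius < raster.cell_size / 2:
        warnings.warn("focal radius smaller than half a cell; returning input")
        return raster.like(raster.values.copy())
    foot = circular_footprint(radius, raster.cell_size).astype(float)
    valid = raster.mask.astype(float)
    vals = np.where(raster.mask, raster.values, 0.0)
    num = ndimage.convolve(vals, foot, mode="constant", cval=0.0)
    den = ndimage.convolve(valid, foot, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    out[~raster.mask] = np.nan
    return raster.like(out)


# ----------------------------------------------------------------------
# moving-window landscape metrics
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class WindowMetricSpec:
    """A FRAGSTATS-style moving-window metric request.

    metric : one of PLAND, LPI, PD, ED, SHDI, AI
    level : "landscape" or "class"; ``focal_class`` is required at class
        level (PLAND/LPI) and forbidden at landscape level.
    radius : window radius in meters.
    """

    metric: str
    radius: float
    level: str = "landscape"
    focal_class: int | None = None

    def __post_init__(self):
        if self.metric not in {"PLAND", "LPI", "PD", "ED", "SHDI", "AI"}:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.level not in {"landscape", "class"}:
            raise ValueError("level must be 'landscape' or 'class'")
        if (self.level == "class") != (self.focal_class is not None):
            raise ValueError("focal_class required iff level == 'class'")


def _max_like_adjacencies(n_cells: int) -> int:
    """Largest possible single-count like-adjacency count for a class of
    ``n_cells`` cells packed into the most compact (near-square) patch."""
    n = int(math.floor(math.sqrt(n_cells)))
    m = n_cells - n * n
    if m == 0:
        return 2 * n * (n - 1)
    if m <= n:
        return 2 * n * (n - 1) + 2 * m - 1
    return 2 * n * (n - 1) + 2 * m - 2


def _window_values(metric: str, win: np.ndarray, valid: np.ndarray,
                   cell_size: float, focal_class: int | None) -> float:
    """Compute one metric on a square window array; ``valid`` marks cells
    inside the circular footprint and holding data."""
    n_valid = int(valid.sum())
    if n_valid == 0:
        return np.nan
    area_m2 = n_valid * cell_size ** 2
    area_ha = area_m2 / 1e4

    if metric == "PLAND":
        return 100.0 * float(np.sum(valid & (win == focal_class))) / n_valid

    if metric == "LPI":
        m = valid & (win == focal_class)
        if not m.any():
            return 0.0
        lab, nlab = ndimage.label(m, structure=_EIGHT)
        largest = np.bincount(lab.ravel())[1:].max()
        return 100.0 * float(largest) / n_valid

    if metric == "PD":
        classes = np.unique(win[valid])
        n_patches = 0
        for c in classes:
            _, nlab = ndimage.label(valid & (win == c), structure=_EIGHT)
            n_patches += nlab
        return n_patches / area_ha * 100.0  # patches per 100 ha

    if metric == "ED":
        edge = 0
        vc = np.where(valid, win, np.nan)
        h = valid[:, :-1] & valid[:, 1:] & (vc[:, :-1] != vc[:, 1:])
        v = valid[:-1, :] & valid[1:, :] & (vc[:-1, :] != vc[1:, :])
        edge = (h.sum() + v.sum()) * cell_size
        return float(edge) / area_ha  # m per ha

    if metric == "SHDI":
        _, counts = np.unique(win[valid], return_counts=True)
        p = counts / n_valid
        return float(-(p * np.log(p)).sum())

    if metric == "AI":
        classes, counts = np.unique(win[valid], return_counts=True)
        total = 0.0
        for c, n_c in zip(classes, counts):
            m = valid & (win == c)
            g = (np.sum(m[:, :-1] & m[:, 1:]) + np.sum(m[:-1, :] & m[1:, :]))
            gmax = _max_like_adjacencies(int(n_c))
            ratio = (g / gmax) if gmax > 0 else 1.0  # single cell: compact
            total += (n_c / n_valid) * ratio
        return 100.0 * total

    raise ValueError(metric)


def window_metric(landcover: RasterGrid, spec: WindowMetricSpec,
                  valid_classes: Iterable[int] | None = None) -> RasterGrid:
    """Moving-window landscape metric over a categorical raster.

    Each output cell is the metric computed over the circular window of
    ``spec.radius`` centered on it, truncated at the raster edge, over valid
    cells only.  Unknown class codes raise a ``ValueError`` when
    ``valid_classes`` is given.
    """
    lc = landcover.values
    mask = landcover.mask
    codes = np.unique(lc[mask])
    if valid_classes is not None:
        bad = set(codes.astype(int)) - set(int(c) for c in valid_classes)
        if bad:
            raise ValueError(f"unknown land-cover class codes: {sorted(bad)}")
    foot = circular_footprint(spec.radius, landcover.cell_size)
    k = foot.shape[0] // 2
    nr, nc = lc.shape
    lcp = np.pad(lc, k, mode="constant", constant_values=np.nan)
    maskp = np.pad(mask, k, mode="constant", constant_values=False)
    out = np.full((nr, nc), np.nan)
    for r in range(nr):
        for c in range(nc):
            if not mask[r, c]:
                continue
            win = lcp[r:r + 2 * k + 1, c:c + 2 * k + 1]
            valid = maskp[r:r + 2 * k + 1, c:c + 2 * k + 1] & foot
            out[r, c] = _window_values(spec.metric, win, valid,
                                       landcover.cell_size, spec.focal_class)
    return landcover.like(out)


# ----------------------------------------------------------------------
# feature distance and density
# ----------------------------------------------------------------------
def distance_to_features(features: Sequence, grid_template: RasterGrid) -> RasterGrid:
    """Per-cell Euclidean distance (m) from the cell center to the nearest
    feature geometry (shapely points/lines/polygons)."""
    geoms = list(features)
    if len(geoms) == 0:
        raise ValueError("feature set is empty; distance layer undefined")
    union = shapely.union_all([shapely.geometry.shape(g) if isinstance(g, dict)
                               else g for g in geoms])
    X, Y = grid_template.cell_centers()
    pts = shapely.points(X.ravel(), Y.ravel())
    d = shapely.distance(pts, union).reshape(grid_template.shape)
    d = np.where(grid_template.mask, d, np.nan)
    return grid_template.like(d)


def feature_density(features: Sequence, radius: float,
                    grid_template: RasterGrid) -> RasterGrid:
    """Moving-window feature density.

    Point features: count of points within ``radius`` of the cell center,
    divided by the window area (points per km^2).  Line features: total
    polyline length within the window, divided by the window area (km of
    line per km^2).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    area_km2 = math.pi * (radius / 1000.0) ** 2
    X, Y = grid_template.cell_centers()
    geoms = [shapely.geometry.shape(g) if isinstance(g, dict) else g
             for g in features]
    if len(geoms) == 0:
        out = np.zeros(grid_template.shape)
        out[~grid_template.mask] = np.nan
        return grid_template.like(out)

    kinds = {g.geom_type for g in geoms}
    if kinds <= {"Point", "MultiPoint"}:
        coords = np.array([[g.x, g.y] for g in geoms])
        tree = cKDTree(coords)
        counts = tree.query_ball_point(
            np.column_stack([X.ravel(), Y.ravel()]), r=radius,
            return_length=True)
        out = counts.reshape(grid_template.shape) / area_km2
    else:
        union = shapely.union_all(geoms)
        pts = shapely.points(X.ravel(), Y.ravel())
        discs = shapely.buffer(pts, radius, quad_segs=32)
        inter = shapely.intersection(discs, union)
        lengths = shapely.length(inter).reshape(grid_template.shape)
        out = (lengths / 1000.0) / area_km2
    out = np.where(grid_template.mask, out, np.nan)
    return grid_template.like(out)


# ----------------------------------------------------------------------
# the multiscale stack
# ----------------------------------------------------------------------
@dataclass
class CovariateStack:
    """Named covariate layers on a shared grid.

    Scaled layers are keyed ``VAR_scale`` (e.g. ``BAM_1000``); distance
    layers carry no scale suffix (``Disvil``).
    """

    layers: dict[str, RasterGrid] = field(default_factory=dict)
    scales: tuple[int, ...] = STANDARD_SCALES

    def add(self, name: str, grid: RasterGrid) -> None:
        if self.layers:
            tmpl = next(iter(self.layers.values()))
            if not grid.aligned_with(tmpl):
                raise ValueError(f"layer {name!r} is not aligned with the stack")
        self.layers[name] = grid

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __len__(self) -> int:
        return len(self.layers)

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def template(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    def variables(self) -> dict[str, list[int]]:
        """Base variable -> sorted list of scales present (empty for
        unscaled layers)."""
        out: dict[str, list[int]] = {}
        for name in self.layers:
            base, scale = split_layer_name(name)
            out.setdefault(base, [])
            if scale is not None:
                out[base].append(scale)
        return {k: sorted(v) for k, v in out.items()}

    def layer_for(self, variable: str, scale: int | None) -> RasterGrid:
        name = variable if scale is None else f"{variable}_{scale}"
        if name not in self.layers:
            raise KeyError(f"variable {variable!r} missing at scale {scale}")
        return self.layers[name]

    def sample(self, x, y, names: Sequence[str] | None = None) -> pd.DataFrame:
        """Layer values at point locations, as a DataFrame (one column per
        layer, one row per point)."""
        names = list(names) if names is not None else self.names
        data = {n: self.layers[n].sample(x, y) for n in names}
        return pd.DataFrame(data)

    # ---------------- I/O ----------------
    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, grid in self.layers.items():
            grid.to_ascii(path / f"{name}.asc")

    @classmethod
    def from_dir(cls, path: str | Path) -> "CovariateStack":
        path = Path(path)
        stack = cls(layers={}, scales=())
        scales: set[int] = set()
        for f in sorted(path.glob("*.asc")):
            name = f.stem
            stack.layers[name] = RasterGrid.from_ascii(f)
            _, scale = split_layer_name(name)
            if scale is not None:
                scales.add(scale)
        stack.scales = tuple(sorted(scales))
        return stack


def split_layer_name(name: str) -> tuple[str, int | None]:
    """Split ``"BAM_1000"`` into ``("BAM", 1000)``; unscaled names pass
    through with ``None``."""
    if "_" in name:
        base, tail = name.rsplit("_", 1)
        if tail.isdigit():
            return base, int(tail)
    return name, None


_CONTINUOUS = ("ELE", "SLP", "ASP", "TRI", "NPP", "BAM")
_LANDSCAPE_METRICS = ("AI", "ED", "PD", "SHDI")
_CLASS_METRICS = {"CNF": ("LPI", "PLAND"), "CBF": ("LPI", "PLAND")}


def build_multiscale_stack(
    base_layers: Mapping[str, object],
    scales: Sequence[int] = STANDARD_SCALES,
    *,
    landcover_classes: Mapping[str, int] | None = None,
    include_window_metrics: bool = True,
) -> CovariateStack:
    """Expand base layers into the full multiscale covariate stack.

    ``base_layers`` maps names to inputs: continuous rasters under
    ``ELE/SLP/ASP/TRI/NPP/BAM`` (each focal-meaned at every scale), a
    categorical raster under ``LANDCOVER`` (moving-window metrics at every
    scale), point/line feature sequences under ``villages``,
    ``roads_major``, ``roads_minor`` (densities at every scale, distances
    once).  Any subset of these keys may be supplied; missing keys simply
    produce no layers.

    Distance layers (``Disvil``, ``Dismajor``, ``Disunpaved``) carry no
    scale suffix.
    """
    scales = tuple(int(s) for s in scales)
    if not scales:
        raise ValueError("at least one scale required")
    grids = [v for v in base_layers.values() if isinstance(v, RasterGrid)]
    if not grids:
        raise ValueError("no raster layer supplied")
    tmpl = grids[0]
    for g in grids:
        if not g.aligned_with(tmpl):
            raise ValueError("base raster layers are not aligned")

    stack = CovariateStack(layers={}, scales=scales)

    for var in _CONTINUOUS:
        if var in base_layers:
            for s in scales:
                stack.add(f"{var}_{s}", focal_mean(base_layers[var], s))

    if include_window_metrics and "LANDCOVER" in base_layers:
        lc = base_layers["LANDCOVER"]
        cls = dict(landcover_classes or {})
        for s in scales:
            for metric in _LANDSCAPE_METRICS:
                spec = WindowMetricSpec(metric, s)
                stack.add(f"{metric}_{s}", window_metric(lc, spec))
            for cname, metrics in _CLASS_METRICS.items():
                if cname not in cls:
                    continue
                for metric in metrics:
                    spec = WindowMetricSpec(metric, s, level="class",
                                            focal_class=cls[cname])
                    stack.add(f"{metric}_{cname}_{s}", window_metric(lc, spec))

    if "villages" in base_layers:
        feats = list(base_layers["villages"])
        for s in scales:
            stack.add(f"Densvil_{s}", feature_density(feats, s, tmpl))
        if feats:
            stack.add("Disvil", distance_to_features(feats, tmpl))
    road_parts = []
    for key in ("roads_major", "roads_minor"):
        if key in base_layers:
            road_parts.extend(list(base_layers[key]))
    if road_parts:
        for s in scales:
            stack.add(f"Densrd_{s}", feature_density(road_parts, s, tmpl))
    if base_layers.get("roads_major"):
        stack.add("Dismajor", distance_to_features(
            list(base_layers["roads_major"]), tmpl))
    if base_layers.get("roads_minor"):
        stack.add("Disunpaved", distance_to_features(
            list(base_layers["roads_minor"]), tmpl))

    return stack
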