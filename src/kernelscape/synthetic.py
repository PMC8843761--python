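"""Synthetic mountain landscapes with a known generative suitability model.

The generator emulates the structure of a 250-m projected raster study
area: a smooth correlated elevation field spanning roughly 500–5,000 m, a
binary understory-bamboo layer concentrated in a mid-elevation band,
villages and roads biased toward low elevation, protected-area polygons,
and species occurrences drawn from a *known* suitability surface composed
of scale-specific effects (fine-scale bamboo and elevation responses,
coarse-scale anthropogenic density).  Because the generative model is
known, the downstream pipeline can be tested for parameter and scale
recovery without any external data.

All generators are fully deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import LineString, Point, Polygon, mapping

from .covariates import focal_mean
from .raster import RasterGrid

__all__ = [
    "LandscapeConfig",
    "EffectTerm",
    "TrueSuitabilityModel",
    "SyntheticLandscape",
    "generate_terrain",
    "generate_bamboo",
    "generate_features",
    "generate_landscape",
    "sample_occurrences",
    "default_true_model",
]


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic landscape generator.

    The defaults describe a 50 × 50 km mountain block at 250-m resolution
    with terrain relief spanning the elevations where the focal species and
    its food plant occur, and anthropogenic features (villages, roads)
    concentrated in valleys.
    """

    seed: int = 0
    width: int = 200              # cells (east-west)
    height: int = 200             # cells (north-south)
    cell_size: float = 250.0      # m
    relief_amplitude: float = 2250.0   # m, half the elevation span
    base_elevation: float = 2750.0     # m, landscape mean elevation
    correlation_length: float = 20.0   # cells, terrain autocorrelation range
    roughness: float = 1.2        # relative amplitude of fine-scale relief
    n_villages: int = 60
    village_elevation_bias: float = 3.0   # exp decay of village weight with
                                          # relative elevation; 0 = uniform
    n_roads: int = 4
    bamboo_elevation_band: tuple[float, float] = (2000.0, 3200.0)
    bamboo_peak_prob: float = 0.85
    pa_fraction: float = 0.3      # target protected-area cover fraction

    def __post_init__(self):
        if self.width < 40 or self.height < 40:
            raise ValueError("landscape extent must be at least 40x40 cells")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")


@dataclass(frozen=True)
class EffectTerm:
    """One scale-specific effect in the generative suitability model.

    ``layer`` names a base layer (``ELE``, ``BAM``, ``Densvil`` ...),
    measured as its focal mean within ``scale`` meters.  ``shape`` is
    ``"linear"`` (coefficient applies to the standardized layer) or
    ``"unimodal"`` (Gaussian response peaking at ``optimum`` with standard
    deviation ``width`` in the layer's units).
    """

    layer: str
    scale: int
    shape: Literal["linear", "unimodal"]
    coefficient: float
    optimum: float | None = None
    width: float | None = None

    def __post_init__(self):
        if self.shape == "unimodal" and (self.optimum is None or self.width is None):
            raise ValueError("unimodal terms need optimum and width")


@dataclass
class TrueSuitabilityModel:
    """Known generative suitability: logistic link over scale-specific terms.

    Each term contributes to a linear predictor which is squashed to [0, 1]
    with a logistic link, so the surface is a valid suitability everywhere.
    """

    terms: tuple[EffectTerm, ...]
    intercept: float = 0.0

    def evaluate(self, base_layers: dict[str, RasterGrid]) -> RasterGrid:
        """Suitability surface from base layers (focal means computed here)."""
        tmpl = next(iter(base_layers.values()))
        lp = np.full(tmpl.shape, self.intercept, dtype=float)
        for t in self.terms:
            if t.layer not in base_layers:
                raise KeyError(f"true model needs base layer {t.layer!r}")
            lay = focal_mean(base_layers[t.layer], t.scale).values
            if t.shape == "linear":
                mu = np.nanmean(lay)
                sd = np.nanstd(lay)
                z = (lay - mu) / sd if sd > 0 else np.zeros_like(lay)
                lp += t.coefficient * z
            else:
                lp += t.coefficient * np.exp(
                    -0.5 * ((lay - t.optimum) / t.width) ** 2)
        suit = 1.0 / (1.0 + np.exp(-lp))
        suit[~tmpl.mask] = np.nan
        return tmpl.like(suit)


def default_true_model() -> TrueSuitabilityModel:
    """The study-condition generative model: unimodal elevation response
    peaking at 2,600 m at the 1-km scale, positive bamboo response at 1 km,
    and negative village-density response at 4 km.

    Effect strengths are deliberately strong and the elevation response
    narrow (width 200 m): univariate scale selection can only distinguish
    adjacent focal scales when the response is sharp relative to the
    difference between neighbouring focal-mean fields.
    """
    return TrueSuitabilityModel(
        terms=(
            EffectTerm("ELE", 1000, "unimodal", 12.0, optimum=2600.0,
                       width=200.0),
            EffectTerm("BAM", 1000, "linear", 3.0),
            EffectTerm("Densvil", 4000, "linear", -5.0),
        ),
        intercept=-5.0,
    )


# ----------------------------------------------------------------------
# terrain
# ----------------------------------------------------------------------
def generate_terrain(config: LandscapeConfig) -> RasterGrid:
    """Smooth correlated elevation field (spectrally filtered Gaussian
    random field), deterministic per seed.

    The field mixes a long-range component (autocorrelation range
    ``config.correlation_length`` cells) with a fine-scale roughness
    component an eighth that range, weighted by ``config.roughness`` — real
    mountain terrain has relief at both ridge and gully scales — then is
    rescaled to ``base_elevation ± relief_amplitude``.
    """
    rng = np.random.default_rng(config.seed)
    nr, nc = config.height, config.width
    noise = rng.standard_normal((nr, nc))
    if config.relief_amplitude == 0:
        vals = np.full((nr, nc), config.base_elevation)
        return RasterGrid(vals, config.cell_size, (0.0, nr * config.cell_size))
    # Gaussian-kernel smoothing: semivariogram range ~ 2*sigma for a
    # Gaussian covariance model; pick sigma = corr_length / 2.
    sigma = max(config.correlation_length / 2.0, 0.5)
    long_rng = ndimage.gaussian_filter(noise, sigma, mode="reflect")
    long_rng /= max(long_rng.std(), 1e-12)
    fine = ndimage.gaussian_filter(rng.standard_normal((nr, nc)),
                                   max(sigma / 8.0, 0.5), mode="reflect")
    fine /= max(fine.std(), 1e-12)
    fld = long_rng + config.roughness * fine
    fld -= fld.mean()
    peak = np.abs(fld).max()
    if peak > 0:
        fld = fld / peak * config.relief_amplitude
    vals = config.base_elevation + fld
    return RasterGrid(vals, config.cell_size, (0.0, nr * config.cell_size))


# ----------------------------------------------------------------------
# bamboo
# ----------------------------------------------------------------------
def generate_bamboo(config: LandscapeConfig, terrain: RasterGrid,
                    seed_offset: int = 1) -> RasterGrid:
    """Binary bamboo-presence layer.

    Bernoulli draw with probability peaked inside the configured elevation
    band and decaying outside it, followed by a 3x3 majority smooth so the
    map has patch structure rather than salt-and-pepper noise.
    """
    rng = np.random.default_rng((config.seed, seed_offset))
    lo, hi = config.bamboo_elevation_band
    center = 0.5 * (lo + hi)
    halfwidth = 0.5 * (hi - lo)
    z = terrain.values
    p = config.bamboo_peak_prob * np.exp(-0.5 * ((z - center) / halfwidth) ** 2)
    draw = rng.random(z.shape) < p
    smoothed = ndimage.uniform_filter(draw.astype(float), size=3) > 0.5
    vals = smoothed.astype(float)
    vals[~terrain.mask] = np.nan
    return terrain.like(vals)


# ----------------------------------------------------------------------
# vector features
# ----------------------------------------------------------------------
@dataclass
class FeatureSet:
    villages: list[Point]
    roads: list[LineString]
    protected_areas: list[Polygon]


def generate_features(config: LandscapeConfig, terrain: RasterGrid,
                      seed_offset: int = 2) -> FeatureSet:
    """Villages (points, biased to low elevation), roads (polylines crossing
    the extent, following low ground), and protected areas (polygons covering
    about ``pa_fraction`` of the extent, placed on high ground)."""
    rng = np.random.default_rng((config.seed, seed_offset))
    xmin, ymin, xmax, ymax = terrain.bounds
    z = terrain.values

    # villages: sample cells with weight decaying in elevation
    villages: list[Point] = []
    if config.n_villages > 0:
        zmin, zmax = np.nanmin(z), np.nanmax(z)
        span = max(zmax - zmin, 1.0)
        w = np.exp(-config.village_elevation_bias * (z - zmin) / span)
        w[~terrain.mask] = 0.0
        w = w.ravel() / w.sum()
        idx = rng.choice(z.size, size=config.n_villages, replace=False, p=w)
        rows, cols = np.unravel_index(idx, z.shape)
        x, y = terrain.xy(rows, cols)
        jx = rng.uniform(-0.5, 0.5, config.n_villages) * terrain.cell_size
        jy = rng.uniform(-0.5, 0.5, config.n_villages) * terrain.cell_size
        villages = [Point(px, py) for px, py in zip(x + jx, y + jy)]

    # roads: polylines crossing the full extent with gentle jitter
    roads: list[LineString] = []
    for k in range(config.n_roads):
        horizontal = bool(rng.integers(2))
        n_vert = 8
        if horizontal:
            xs = np.linspace(xmin, xmax, n_vert)
            y0 = rng.uniform(ymin + 0.1 * (ymax - ymin), ymax - 0.1 * (ymax - ymin))
            ys = y0 + rng.normal(0, 0.03 * (ymax - ymin), n_vert).cumsum()
            ys = np.clip(ys, ymin, ymax)
        else:
            ys = np.linspace(ymin, ymax, n_vert)
            x0 = rng.uniform(xmin + 0.1 * (xmax - xmin), xmax - 0.1 * (xmax - xmin))
            xs = x0 + rng.normal(0, 0.03 * (xmax - xmin), n_vert).cumsum()
            xs = np.clip(xs, xmin, xmax)
        roads.append(LineString(np.column_stack([xs, ys])))

    # protected areas: grow random discs until the target fraction is covered
    pas: list[Polygon] = []
    if config.pa_fraction >= 1.0:
        pas = [shapely.box(xmin, ymin, xmax, ymax)]
    elif config.pa_fraction > 0:
        extent_area = (xmax - xmin) * (ymax - ymin)
        target = config.pa_fraction * extent_area
        covered = 0.0
        box = shapely.box(xmin, ymin, xmax, ymax)
        for _ in range(200):
            if covered >= target:
                break
            cx = rng.uniform(xmin, xmax)
            cy = rng.uniform(ymin, ymax)
            r = rng.uniform(0.08, 0.18) * min(xmax - xmin, ymax - ymin)
            disc = Point(cx, cy).buffer(r, quad_segs=16).intersection(box)
            pas.append(disc)
            covered = shapely.union_all(pas).area

    return FeatureSet(villages=villages, roads=roads, protected_areas=pas)


# ----------------------------------------------------------------------
# occurrences
# ----------------------------------------------------------------------
def sample_occurrences(true_suitability: RasterGrid, n: int = 528,
                       seed: int = 0) -> pd.DataFrame:
    """Presence points drawn with probability proportional to suitability.

    Cells are drawn without replacement with weights proportional to the
    suitability surface; each point is jittered uniformly within its cell.
    Default ``n`` mirrors a national-survey-scale occurrence count before
    spatial thinning.

    Returns a DataFrame with columns ``x, y, label`` (label ``"presence"``).
    """
    rng = np.random.default_rng(seed)
    s = true_suitability.values
    w = np.where(true_suitability.mask, s, 0.0).ravel()
    w = np.where(w > 0, w, 0.0)
    n_positive = int((w > 0).sum())
    if n > n_positive:
        raise ValueError(
            f"requested {n} occurrences but only {n_positive} cells have "
            "positive suitability")
    idx = rng.choice(w.size, size=n, replace=False, p=w / w.sum())
    rows, cols = np.unravel_index(idx, s.shape)
    x, y = true_suitability.xy(rows, cols)
    cs = true_suitability.cell_size
    x = x + rng.uniform(-0.5, 0.5, n) * cs
    y = y + rng.uniform(-0.5, 0.5, n) * cs
    return pd.DataFrame({"x": x, "y": y, "label": "presence"})


# ----------------------------------------------------------------------
# one-call landscape bundle
# ----------------------------------------------------------------------
@dataclass
class SyntheticLandscape:
    """Everything the pipeline needs, generated from one config."""

    config: LandscapeConfig
    terrain: RasterGrid
    bamboo: RasterGrid
    npp: RasterGrid
    landcover: RasterGrid
    features: FeatureSet
    true_model: TrueSuitabilityModel
    true_suitability: RasterGrid
    occurrences: pd.DataFrame

    def base_layers(self) -> dict[str, object]:
        from .covariates import terrain_derivatives
        slope, asp, tri, slp = terrain_derivatives(self.terrain)
        return {
            "ELE": self.terrain,
            "SLP": slp,
            "ASP": asp,
            "TRI": tri,
            "NPP": self.npp,
            "BAM": self.bamboo,
            "LANDCOVER": self.landcover,
            "villages": self.features.villages,
            "roads_major": self.features.roads[: max(1, len(self.features.roads) // 2)],
            "roads_minor": self.features.roads[max(1, len(self.features.roads) // 2):],
        }

    def write(self, out_dir: str | Path) -> dict:
        """Write rasters (.asc), vectors (GeoJSON) and occurrences (CSV)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.terrain.to_ascii(out / "ELE.asc")
        self.bamboo.to_ascii(out / "BAM.asc")
        self.npp.to_ascii(out / "NPP.asc")
        self.landcover.to_ascii(out / "LANDCOVER.asc")
        self.true_suitability.to_ascii(out / "true_suitability.asc")
        _write_geojson(out / "villages.geojson", self.features.villages)
        _write_geojson(out / "roads.geojson", self.features.roads)
        _write_geojson(out / "protected_areas.geojson",
                       self.features.protected_areas)
        self.occurrences.to_csv(out / "occurrences.csv", index=False)
        return {"out_dir": str(out)}


def _write_geojson(path: Path, geoms: Sequence) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"id": i},
             "geometry": mapping(g)}
            for i, g in enumerate(geoms)
        ],
    }
    path.write_text(json.dumps(fc))


def read_geojson(path: str | Path) -> list:
    data = json.loads(Path(path).read_text())
    return [shapely.geometry.shape(f["geometry"]) for f in data["features"]]


def generate_landscape(config: LandscapeConfig | None = None,
                       true_model: TrueSuitabilityModel | None = None,
                       n_occurrences: int = 528) -> SyntheticLandscape:
    """Generate the full synthetic landscape bundle from one config."""
    config = config or LandscapeConfig()
    true_model = true_model or default_true_model()
    terrain = generate_terrain(config)
    bamboo = generate_bamboo(config, terrain)
    features = generate_features(config, terrain)

    rng = np.random.default_rng((config.seed, 3))
    # NPP: productivity declining with elevation plus smooth noise
    z = terrain.values
    zmin, zmax = np.nanmin(z), np.nanmax(z)
    span = max(zmax - zmin, 1.0)
    npp_vals = 900.0 * (1.0 - 0.7 * (z - zmin) / span)
    npp_vals += ndimage.gaussian_filter(
        rng.standard_normal(z.shape), 4) * 40.0
    npp = terrain.like(np.clip(npp_vals, 0, None))

    # land cover: 7 classes keyed to elevation bands and bamboo
    #   0 crop, 1 shrub, 2 grass, 3 CBF, 4 CNF, 5 OF, 6 nonvegetation
    lc = np.full(z.shape, 5.0)
    lc[z < zmin + 0.15 * span] = 0.0
    lc[(z >= zmin + 0.15 * span) & (z < zmin + 0.3 * span)] = 3.0
    lc[(z >= zmin + 0.3 * span) & (z < zmin + 0.6 * span)] = 4.0
    lc[(z >= zmin + 0.6 * span) & (z < zmin + 0.75 * span)] = 1.0
    lc[(z >= zmin + 0.75 * span) & (z < zmin + 0.9 * span)] = 2.0
    lc[z >= zmin + 0.9 * span] = 6.0
    landcover = terrain.like(lc)

    base = {"ELE": terrain, "BAM": bamboo,
            "Densvil": _village_density_base(features.villages, terrain)}
    true_suit = true_model.evaluate(base)
    occ = sample_occurrences(true_suit, n=n_occurrences,
                             seed=int(np.random.default_rng(
                                 (config.seed, 4)).integers(2 ** 31)))
    return SyntheticLandscape(config, terrain, bamboo, npp, landcover,
                              features, true_model, true_suit, occ)


def _village_density_base(villages, terrain: RasterGrid) -> RasterGrid:
    """Village indicator raster (villages per cell), the base layer whose
    focal mean at scale ``s`` is proportional to village density in the
    ``s``-radius window."""
    vals = np.zeros(terrain.shape)
    for v in villages:
        r, c = terrain.index(v.x, v.y)
        if 0 <= r < terrain.nrows and 0 <= c < terrain.ncols:
            vals[r, c] += 1.0
    vals[~terrain.mask] = np.nan
    return terrain.like(vals)
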