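"""Occurrence preparation: spatial thinning and pseudo-absence generation.

Presence-only survey records are spatially autocorrelated; thinning enforces
a minimum pairwise distance (default 1.2 km, the scale of an average home
range).  Because true absences are unobservable for an elusive forest
species, balanced classifier training uses replicate sets of geographically
stratified pseudo-absences: random points constrained to lie outside a
buffer around every presence (default 3 km, the maximum territory radius),
below an elevation ceiling, off steep slopes, and mutually separated by the
same 1.2-km spacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .raster import RasterGrid

__all__ = [
    "AbsenceConstraints",
    "thin_occurrences",
    "generate_pseudo_absences",
    "read_points_csv",
    "write_points_csv",
]


@dataclass(frozen=True)
class AbsenceConstraints:
    """Constraints on pseudo-absence placement (defaults follow the study
    design: 3-km presence buffer, elevation < 4,000 m, slope < 50 degrees,
    1.2-km within-set spacing, ten replicate sets)."""

    exclusion_radius: float = 3000.0
    max_elevation: float = 4000.0
    max_slope: float = 50.0
    min_spacing: float = 1200.0
    n_sets: int = 10

    def __post_init__(self):
        for name in ("exclusion_radius", "max_elevation", "max_slope",
                     "min_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")


def thin_occurrences(points: np.ndarray | pd.DataFrame,
                     radius: float = 1200.0) -> pd.DataFrame:
    """Spatially thin points to a minimum pairwise distance.

    Iteratively removes the point with the most neighbors within ``radius``
    until no pair is closer than ``radius``; ties are broken by removing the
    lowest point index.  This greedy rule retains many points while
    guaranteeing the spacing constraint, and is idempotent.

    Parameters
    ----------
    points : (n, 2) array or DataFrame with columns x, y
    radius : float
        Minimum pairwise distance in meters.

    Returns
    -------
    DataFrame with columns ``x, y, label`` ("presence") — the retained
    subset, in original order.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    xy = _as_xy(points)
    n = len(xy)
    if n == 0:
        return pd.DataFrame(columns=["x", "y", "label"])

    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=radius * (1 - 1e-12), output_type="ndarray")
    neigh: dict[int, set[int]] = {i: set() for i in range(n)}
    for a, b in pairs:
        neigh[a].add(b)
        neigh[b].add(a)

    alive = np.ones(n, dtype=bool)
    counts = np.array([len(neigh[i]) for i in range(n)])
    while counts.max(initial=0) > 0:
        i = int(np.argmax(counts))  # argmax takes the lowest index on ties
        alive[i] = False
        counts[i] = 0
        for j in neigh[i]:
            if alive[j]:
                counts[j] -= 1
            neigh[j].discard(i)
        neigh[i] = set()

    kept = xy[alive]
    return pd.DataFrame({"x": kept[:, 0], "y": kept[:, 1],
                         "label": "presence"})


def generate_pseudo_absences(
    presences: np.ndarray | pd.DataFrame,
    constraints: AbsenceConstraints,
    dem: RasterGrid,
    slope: RasterGrid,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> list[pd.DataFrame]:
    """Replicate sets of constrained pseudo-absence points.

    Each of ``constraints.n_sets`` sets holds exactly as many points as
    there are presences.  Every point lies more than ``exclusion_radius``
    from every presence, on cells with elevation below ``max_elevation`` and
    slope below ``max_slope``, and at least ``min_spacing`` from every other
    point in the same set (enforced sequentially).  Points are rejection
    sampled over eligible cells with uniform jitter inside the cell.

    Raises ``RuntimeError`` naming the binding constraint when the eligible
    area is too small.
    """
    if not dem.aligned_with(slope):
        raise ValueError("dem and slope rasters are not aligned")
    xy = _as_xy(presences)
    n_points = len(xy)

    eligible = (dem.mask & slope.mask
                & (dem.values < constraints.max_elevation)
                & (slope.values < constraints.max_slope))
    if not eligible.any():
        raise RuntimeError(
            "no eligible cells: elevation/slope constraints exclude the "
            "entire landscape")

    # exclude cells whose centers are within the presence buffer
    rows, cols = np.nonzero(eligible)
    cx, cy = dem.xy(rows, cols)
    if n_points > 0:
        ptree = cKDTree(xy)
        d, _ = ptree.query(np.column_stack([cx, cy]))
        far = d > constraints.exclusion_radius
    else:
        far = np.ones(len(cx), dtype=bool)
    if not far.any():
        raise RuntimeError(
            "no eligible cells: the presence exclusion buffer covers every "
            "cell passing the elevation/slope constraints")
    cand_rows, cand_cols = rows[far], cols[far]

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(constraints.n_sets)
    sets: list[pd.DataFrame] = []
    for rep, cs in enumerate(child_seeds, start=1):
        rng = np.random.default_rng(cs)
        accepted: list[tuple[float, float]] = []
        attempts = 0
        while len(accepted) < n_points:
            if attempts >= max_attempts + n_points:
                raise RuntimeError(
                    f"replicate {rep}: could not place {n_points} points "
                    f"after {attempts} attempts; the within-set minimum "
                    f"spacing of {constraints.min_spacing} m is the binding "
                    "constraint for the available eligible area")
            attempts += 1
            i = rng.integers(len(cand_rows))
            x, y = dem.xy(cand_rows[i], cand_cols[i])
            x = float(x) + float(rng.uniform(-0.5, 0.5)) * dem.cell_size
            y = float(y) + float(rng.uniform(-0.5, 0.5)) * dem.cell_size
            if n_points and _min_dist_sq(xy, x, y) <= constraints.exclusion_radius ** 2:
                continue
            if accepted:
                acc = np.asarray(accepted)
                if _min_dist_sq(acc, x, y) < constraints.min_spacing ** 2:
                    continue
            accepted.append((x, y))
        acc = np.asarray(accepted)
        sets.append(pd.DataFrame({
            "x": acc[:, 0], "y": acc[:, 1],
            "label": "pseudo_absence", "replicate_id": rep}))
    return sets


def _min_dist_sq(points: np.ndarray, x: float, y: float) -> float:
    d = (points[:, 0] - x) ** 2 + (points[:, 1] - y) ** 2
    return float(d.min())


def _as_xy(points) -> np.ndarray:
    if isinstance(points, pd.DataFrame):
        return points[["x", "y"]].to_numpy(dtype=float)
    arr = np.asarray(points, dtype=float)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array or x/y DataFrame")
    return arr


def write_points_csv(path: str | Path, *frames: pd.DataFrame) -> None:
    df = pd.concat(frames, ignore_index=True)
    if "replicate_id" not in df.columns:
        df["replicate_id"] = 0
    df["replicate_id"] = df["replicate_id"].fillna(0).astype(int)
    df.to_csv(path, index=False)


def read_points_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
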