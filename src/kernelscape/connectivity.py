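"""Resistant kernels and factorial least-cost paths on a resistance raster.

The raster is treated as a graph: valid cells are nodes, 8-neighbor
adjacencies are edges, and an edge costs the mean of the two cells'
resistance times the center-to-center distance in meters (x sqrt(2) on
diagonals).  With uniform resistance R = 1 the accumulated cost equals
geometric distance, which calibrates the cost unit: 1 cost unit = 1 meter
traversed through ideal habitat.

Two connectivity products are built on Dijkstra cost distances:

* **resistant kernels** — a dispersal kernel decaying with accumulated cost
  from each source, truncated at a movement-ability threshold, summed over
  sources into an expected-density-of-dispersers surface;
* **factorial least-cost paths** — least-cost paths between every pair of
  sources (up to a cost ceiling), each rasterized, Gaussian-smoothed and
  summed into a corridor-intensity surface.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import dijkstra as _dijkstra

from .raster import RasterGrid

__all__ = [
    "CostGraph",
    "KernelSurface",
    "CorridorDensity",
    "build_cost_graph",
    "cost_distance",
    "resistant_kernel",
    "least_cost_path",
    "factorial_lcp_density",
]

logger = logging.getLogger(__name__)

UNREACHED = np.inf


@dataclass
class CostGraph:
    """Sparse 8-neighbor cost graph over valid raster cells."""

    matrix: csr_matrix
    node_ids: np.ndarray      # grid of node indices, -1 on nodata
    cells: np.ndarray         # (n_nodes, 2) row/col per node
    grid: RasterGrid

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def node_of_cell(self, row: int, col: int) -> int:
        nid = int(self.node_ids[row, col])
        if nid < 0:
            raise ValueError(f"cell ({row}, {col}) is nodata")
        return nid

    def node_of_point(self, x: float, y: float) -> int:
        row, col = self.grid.index(x, y)
        if not (0 <= row < self.grid.nrows and 0 <= col < self.grid.ncols):
            raise ValueError(f"point ({x}, {y}) is outside the raster")
        nid = int(self.node_ids[row, col])
        if nid < 0:
            raise ValueError(f"source point ({x}, {y}) falls on a nodata cell")
        return nid


def build_cost_graph(resistance: RasterGrid,
                     connectivity: int = 8) -> CostGraph:
    """Build the cost graph (edge weight = mean resistance x distance)."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    r = resistance.values
    valid = resistance.mask
    if valid.any() and np.nanmin(r) <= 0:
        raise ValueError("resistance must be strictly positive")
    nr, nc = r.shape
    ids = np.full((nr, nc), -1, dtype=np.int64)
    ids[valid] = np.arange(int(valid.sum()))
    rows, cols = np.nonzero(valid)
    cells = np.column_stack([rows, cols])

    cs = resistance.cell_size
    shifts = [(0, 1, cs), (1, 0, cs)]
    if connectivity == 8:
        d = cs * math.sqrt(2.0)
        shifts += [(1, 1, d), (1, -1, d)]

    src, dst, wts = [], [], []
    for dr, dc, dist in shifts:
        r0, r1 = max(0, -dr), min(nr, nr - dr)
        c0, c1 = max(0, -dc), min(nc, nc - dc)
        a = ids[r0:r1, c0:c1]
        b = ids[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        ra = r[r0:r1, c0:c1]
        rb = r[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        ok = (a >= 0) & (b >= 0)
        src.append(a[ok])
        dst.append(b[ok])
        wts.append(0.5 * (ra[ok] + rb[ok]) * dist)

    n = int(valid.sum())
    mat = coo_matrix(
        (np.concatenate(wts), (np.concatenate(src), np.concatenate(dst))),
        shape=(n, n)).tocsr()
    return CostGraph(matrix=mat, node_ids=ids, cells=cells, grid=resistance)


def _source_nodes(graph: CostGraph, sources) -> list[int]:
    nodes = []
    for s in np.atleast_2d(np.asarray(sources, dtype=float)):
        nodes.append(graph.node_of_point(s[0], s[1]))
    return nodes


def cost_distance(resistance: RasterGrid | CostGraph, sources,
                  max_cost: float = np.inf) -> list[RasterGrid]:
    """Dijkstra accumulated cost from each source point, truncated at
    ``max_cost`` (unreached cells are ``inf``); cost at the source is 0.

    ``sources`` is an (n, 2) array of projected x/y coordinates (or a
    DataFrame slice thereof).  A source on a nodata cell raises an error
    naming the point.
    """
    if max_cost <= 0:
        raise ValueError("max_cost must be positive")
    graph = (resistance if isinstance(resistance, CostGraph)
             else build_cost_graph(resistance))
    nodes = _source_nodes(graph, sources)
    dist = _dijkstra(graph.matrix, directed=False, indices=nodes,
                     limit=max_cost)
    out = []
    for k in range(len(nodes)):
        surf = np.full(graph.grid.shape, UNREACHED)
        surf[graph.node_ids >= 0] = dist[k]
        surf[~graph.grid.mask] = np.nan
        out.append(graph.grid.like(surf))
    return out


@dataclass
class KernelSurface:
    """Summed per-source dispersal kernels."""

    surface: RasterGrid
    threshold: float
    n_sources: int


def resistant_kernel(resistance: RasterGrid | CostGraph, sources,
                     threshold: float = 6000.0,
                     shape: str = "linear") -> KernelSurface:
    """Resistant-kernel surface: per-source kernel decaying with cost
    distance, truncated at ``threshold`` cost units, summed over sources.

    ``shape="linear"`` gives k = max(0, 1 - cost/threshold) (an isolated
    source cell scores exactly 1); ``shape="gaussian"`` gives a Gaussian
    decay with 3 sigma at the threshold, also truncated there.
    """
    if shape not in ("linear", "gaussian"):
        raise ValueError("kernel shape must be 'linear' or 'gaussian'")
    sources = np.atleast_2d(np.asarray(sources, dtype=float))
    if sources.size == 0:
        raise ValueError("resistant_kernel requires at least one source")
    graph = (resistance if isinstance(resistance, CostGraph)
             else build_cost_graph(resistance))
    nodes = _source_nodes(graph, sources)
    total = np.zeros(graph.n_nodes)
    chunk = 64
    for i in range(0, len(nodes), chunk):
        dist = _dijkstra(graph.matrix, directed=False,
                         indices=nodes[i:i + chunk], limit=threshold)
        dist = np.atleast_2d(dist)
        reach = np.isfinite(dist)
        if shape == "linear":
            k = np.where(reach, 1.0 - dist / threshold, 0.0)
        else:
            sigma = threshold / 3.0
            k = np.where(reach, np.exp(-0.5 * (dist / sigma) ** 2), 0.0)
        k = np.clip(k, 0.0, None)
        total += k.sum(axis=0)
    surf = np.full(graph.grid.shape, np.nan)
    surf[graph.grid.mask] = 0.0
    surf[graph.node_ids >= 0] = total
    surf[~graph.grid.mask] = np.nan
    return KernelSurface(surface=graph.grid.like(surf), threshold=threshold,
                         n_sources=len(nodes))


def least_cost_path(resistance: RasterGrid | CostGraph, a, b,
                    max_cost: float = np.inf):
    """Least-cost 8-connected cell path between points ``a`` and ``b``.

    Returns ``(path, cost)`` where ``path`` is a list of (row, col) cells
    from a to b and ``cost`` the accumulated cost; ``(None, inf)`` when b is
    unreachable within ``max_cost``.
    """
    graph = (resistance if isinstance(resistance, CostGraph)
             else build_cost_graph(resistance))
    na = graph.node_of_point(*np.asarray(a, dtype=float))
    nb = graph.node_of_point(*np.asarray(b, dtype=float))
    if na == nb:
        r, c = graph.cells[na]
        return [(int(r), int(c))], 0.0
    dist, pred = _dijkstra(graph.matrix, directed=False, indices=na,
                           limit=max_cost, return_predecessors=True)
    if not np.isfinite(dist[nb]):
        return None, np.inf
    path_nodes = _walk_predecessors(pred, na, nb)
    path = [(int(graph.cells[n][0]), int(graph.cells[n][1]))
            for n in path_nodes]
    return path, float(dist[nb])


def _walk_predecessors(pred: np.ndarray, a: int, b: int) -> list[int]:
    nodes = [b]
    while nodes[-1] != a:
        p = int(pred[nodes[-1]])
        if p < 0:
            raise RuntimeError("broken predecessor chain")
        nodes.append(p)
    return nodes[::-1]


@dataclass
class CorridorDensity:
    """Summed Gaussian-buffered least-cost paths."""

    surface: RasterGrid
    n_paths: int
    bandwidth_cells: float
    max_cost: float


def factorial_lcp_density(resistance: RasterGrid | CostGraph, sources,
                          max_cost: float = 50_000.0,
                          bandwidth_cells: float = 2.0,
                          normalize_per_path: bool = True) -> CorridorDensity:
    """Corridor-intensity surface from all-pairs least-cost paths.

    Every unordered source pair whose least-cost path costs at most
    ``max_cost`` contributes its rasterized path; each path is optionally
    normalized to unit mass, the accumulated surface is convolved with a
    2-D Gaussian of ``bandwidth_cells`` cells, and contributions are summed.
    Pixel values are then interpretable as the (smoothed) frequency of
    least-cost paths passing through the pixel.
    """
    sources = np.atleast_2d(np.asarray(sources, dtype=float))
    if len(sources) < 2:
        raise ValueError("factorial LCP analysis needs at least 2 sources")
    graph = (resistance if isinstance(resistance, CostGraph)
             else build_cost_graph(resistance))
    nodes = _source_nodes(graph, sources)
    accum = np.zeros(graph.grid.shape)
    n_paths = 0
    for i, na in enumerate(nodes[:-1]):
        dist, pred = _dijkstra(graph.matrix, directed=False, indices=na,
                               limit=max_cost, return_predecessors=True)
        for nb in nodes[i + 1:]:
            if nb == na or not np.isfinite(dist[nb]):
                continue
            path_nodes = _walk_predecessors(pred, na, nb)
            mask = np.zeros(graph.grid.shape)
            rc = graph.cells[path_nodes]
            mask[rc[:, 0], rc[:, 1]] = 1.0
            if normalize_per_path:
                mask /= mask.sum()
            accum += mask
            n_paths += 1
    if n_paths == 0:
        warnings.warn("no source pair is mutually reachable within the cost "
                      "ceiling; corridor surface is zero")
    if bandwidth_cells > 0 and n_paths > 0:
        accum = ndimage.gaussian_filter(accum, bandwidth_cells,
                                        mode="constant")
    accum[~graph.grid.mask] = np.nan
    return CorridorDensity(surface=graph.grid.like(accum), n_paths=n_paths,
                           bandwidth_cells=bandwidth_cells, max_cost=max_cost)
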