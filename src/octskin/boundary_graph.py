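"""Boundary delineation as a minimum-cost path through a pixel graph.

Each pixel of a per-class probability map is a graph vertex; 8-connected
neighbors u, v are joined by an edge of weight

    w(u, v) = 2 - (P_u + P_v) + w_min,

so edges between high-probability (boundary-like) pixels are nearly free
while edges through background cost about 2.  Automatic endpoint
initialization appends an all-probability-1 column on each side of the map:
the search then always runs from the top-left to the bottom-right corner,
the path slides vertically along the added columns at negligible cost, and
stripping those columns afterwards leaves the boundary cut across the full
region width.  The search is unconstrained: no monotone-column or
region-band restriction is imposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .preprocess import TargetRegion
from .probmaps import ProbMaps

logger = logging.getLogger(__name__)

__all__ = [
    "WeightParams",
    "BoundaryTrace",
    "edge_weight",
    "augment_endpoints",
    "build_adjacency",
    "shortest_path",
    "trace_from_path",
    "segment_image",
]

#: 8-connected neighborhood offsets (row, col)
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class WeightParams:
    """Edge-weight constants; ``w_min`` keeps every weight strictly positive."""

    w_min: float = 1e-5

    def __post_init__(self) -> None:
        if self.w_min <= 0:
            raise ValueError("w_min must be > 0")


@dataclass
class BoundaryTrace:
    """Per-column boundary row indices for one named boundary."""

    class_id: int
    rows: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.int64)

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        return self.rows.astype(dtype) if dtype is not None else self.rows

    def __len__(self) -> int:
        return self.rows.shape[0]


def edge_weight(p_c: float, p_n: float, params: WeightParams | None = None) -> float:
    """Weight of the edge joining pixels with probabilities ``p_c``, ``p_n``."""
    params = params or WeightParams()
    p_c, p_n = float(p_c), float(p_n)
    if not (0.0 <= p_c <= 1.0 and 0.0 <= p_n <= 1.0):
        raise ValueError(f"probabilities must lie in [0, 1], got ({p_c}, {p_n})")
    return 2.0 - (p_c + p_n) + params.w_min


def augment_endpoints(prob_map: np.ndarray) -> np.ndarray:
    """Append an all-probability-1 column on each side of the map."""
    prob_map = np.asarray(prob_map, dtype=np.float64)
    if prob_map.size == 0:
        raise ValueError("empty probability map")
    ones = np.ones((prob_map.shape[0], 1), dtype=np.float64)
    return np.hstack([ones, prob_map, ones])


def build_adjacency(prob_map: np.ndarray, params: WeightParams | None = None) -> sparse.csr_matrix:
    """Directed 8-connected grid graph in CSR (adjacency-list) form.

    Vertex ids are row-major; each vertex carries out-edges to its at most
    eight neighbors, weighted by :func:`edge_weight` of the two endpoint
    probabilities (hence symmetric).
    """
    params = params or WeightParams()
    p = np.asarray(prob_map, dtype=np.float64)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    h, w = p.shape
    ids = np.arange(h * w, dtype=np.int64).reshape(h, w)
    rows, cols, data = [], [], []
    for dr, dc in _OFFSETS:
        src_r = slice(max(0, -dr), h - max(0, dr))
        src_c = slice(max(0, -dc), w - max(0, dc))
        dst_r = slice(max(0, dr), h - max(0, -dr))
        dst_c = slice(max(0, dc), w - max(0, -dc))
        u = ids[src_r, src_c].ravel()
        v = ids[dst_r, dst_c].ravel()
        wgt = 2.0 - (p[src_r, src_c].ravel() + p[dst_r, dst_c].ravel()) + params.w_min
        rows.append(u)
        cols.append(v)
        data.append(wgt)
    adj = sparse.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(h * w, h * w),
    )
    return adj


def shortest_path(
    adjacency: sparse.csr_matrix,
    shape: tuple[int, int],
    start: int | None = None,
    end: int | None = None,
) -> list[tuple[int, int]]:
    """Minimum-cost path from the top-left to the bottom-right vertex.

    The distance field comes from Dijkstra's algorithm; the path is then
    reconstructed backward from the end node, at each step choosing — among
    neighbors that lie on a minimum-cost path — the lexicographically
    smallest (row, column).  This tie-break makes the returned path
    deterministic even on flat probability fields.
    """
    h, w = shape
    n = h * w
    start = 0 if start is None else start
    end = n - 1 if end is None else end
    dist = _csgraph_dijkstra(adjacency, directed=True, indices=start)
    if not np.isfinite(dist[end]):
        raise ValueError("end node unreachable from start node")

    indptr, indices, data = adjacency.indptr, adjacency.indices, adjacency.data
    path = [end]
    v = end
    for _ in range(4 * n):  # generous guard; dist strictly decreases each step
        if v == start:
            break
        nbrs = indices[indptr[v] : indptr[v + 1]]
        wgts = data[indptr[v] : indptr[v + 1]]
        slack = dist[nbrs] + wgts - dist[v]
        tol = 1e-9 * (1.0 + abs(dist[v]))
        on_path = nbrs[slack <= tol]
        if on_path.size == 0:  # float safety net: take the tightest neighbor
            on_path = nbrs[[int(np.argmin(slack))]]
        v = int(on_path.min())  # row-major id order == (row, col) lexicographic
        path.append(v)
    else:
        raise RuntimeError("path reconstruction did not terminate")
    path.reverse()
    return [(i // w, i % w) for i in path]


def path_cost(path: list[tuple[int, int]], prob_map: np.ndarray, params: WeightParams | None = None) -> float:
    """Total edge weight of a pixel path on a probability map."""
    params = params or WeightParams()
    p = np.asarray(prob_map, dtype=np.float64)
    return float(
        sum(
            edge_weight(p[r0, c0], p[r1, c1], params)
            for (r0, c0), (r1, c1) in zip(path[:-1], path[1:])
        )
    )


def trace_from_path(path: list[tuple[int, int]], region_width: int, how: str = "first") -> np.ndarray:
    """Per-column boundary rows from an augmented-map path.

    Endpoint-column nodes (column 0 and ``region_width + 1``) are dropped;
    each interior column's representative row is the first row visited in
    that column (``how="first"``) or the rounded mean of visited rows
    (``how="mean"``).
    """
    if how not in ("first", "mean"):
        raise ValueError("how must be 'first' or 'mean'")
    visits: dict[int, list[int]] = {}
    for r, c in path:
        if 1 <= c <= region_width:
            visits.setdefault(c - 1, []).append(r)
    missing = [c for c in range(region_width) if c not in visits]
    if missing:
        raise ValueError(f"path never visits region column {missing[0]}")
    if how == "first":
        rows = [visits[c][0] for c in range(region_width)]
    else:
        rows = [int(round(float(np.mean(visits[c])))) for c in range(region_width)]
    return np.asarray(rows, dtype=np.int64)


def segment_boundary(
    prob_map: np.ndarray,
    params: WeightParams | None = None,
    how: str = "first",
) -> np.ndarray:
    """Full graph-search delineation of one class map (region coordinates)."""
    aug = augment_endpoints(prob_map)
    adj = build_adjacency(aug, params)
    path = shortest_path(adj, aug.shape)
    return trace_from_path(path, prob_map.shape[1], how=how)


def segment_image(
    maps: ProbMaps,
    params: WeightParams | None = None,
    region: TargetRegion | None = None,
    how: str = "first",
) -> tuple[BoundaryTrace, BoundaryTrace]:
    """Delineate the SC (class 1) and DEJ (class 2) boundaries independently.

    If ``region`` is given, traces are mapped back to parent-image rows.
    """
    params = params or WeightParams()
    traces = []
    for class_id in (1, 2):
        rows = segment_boundary(maps.class_map(class_id), params, how=how)
        if region is not None:
            rows = region.to_parent_rows(rows)
        traces.append(
            BoundaryTrace(
                class_id=class_id,
                rows=rows,
                provenance=f"graph-search step={maps.step} w_min={params.w_min}",
            )
        )
    return traces[0], traces[1]
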