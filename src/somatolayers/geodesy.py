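"""Geodesic machinery on the cortical patch mesh.

Paths are graph geodesics: vertex chains minimizing total Euclidean edge
length (Dijkstra over the mesh edge graph), not exact polyhedral geodesics.
On top of shortest paths this module provides value sampling with an
optional sliding-window mean, functional border (t-value crossing point)
localization, structural gradient sample extraction along a D1-to-D5 path,
and multidimensional corridor sampling for septa detection between the hand
and face regions.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    CorticalPatchMesh,
    InvalidArgumentError,
    NoCrossingError,
    NoPathError,
)


@dataclass
class GeodesicPath:
    """Ordered vertex chain with cumulative geodesic distance (mm)."""

    vertex_chain: np.ndarray
    cumulative_distance: np.ndarray
    endpoints: tuple[tuple[str, int], tuple[str, int]]

    @property
    def length(self) -> float:
        return float(self.cumulative_distance[-1])

    def __len__(self):
        return len(self.vertex_chain)


def _adjacency(mesh: CorticalPatchMesh):
    """Per-vertex neighbor and edge-length arrays (cached on the mesh)."""
    cached = getattr(mesh, "_adjacency_cache", None)
    if cached is not None:
        return cached
    e = mesh.edges
    w = mesh.edge_lengths
    nbrs: list[list] = [[] for _ in range(mesh.n_vertices)]
    for (a, b), d in zip(e, w):
        nbrs[a].append((int(b), float(d)))
        nbrs[b].append((int(a), float(d)))
    for lst in nbrs:
        lst.sort()
    mesh._adjacency_cache = nbrs
    return nbrs


def shortest_path(mesh: CorticalPatchMesh, src: int, dst: int,
                  allowed: np.ndarray | None = None,
                  labels: tuple[str, str] = ("src", "dst")) -> GeodesicPath:
    """Dijkstra shortest path from ``src`` to ``dst``.

    Ties between equal-cost predecessors break to the lowest vertex index,
    making the returned chain deterministic.  ``allowed`` optionally
    restricts the search to a boolean vertex mask (endpoints must be
    allowed).
    """
    n = mesh.n_vertices
    if not (0 <= src < n and 0 <= dst < n):
        raise InvalidArgumentError("path endpoint outside the mesh")
    if allowed is not None and not (allowed[src] and allowed[dst]):
        raise InvalidArgumentError("path endpoint outside the allowed mask")
    if src == dst:
        return GeodesicPath(np.array([src]), np.array([0.0]),
                            ((labels[0], src), (labels[1], dst)))
    nbrs = _adjacency(mesh)
    dist = np.full(n, np.inf)
    pred = np.full(n, -1, dtype=int)
    done = np.zeros(n, dtype=bool)
    dist[src] = 0.0
    heap = [(0.0, src)]
    tol = 1e-12
    while heap:
        d, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        if u == dst:
            break
        for v, w in nbrs[u]:
            if done[v] or (allowed is not None and not allowed[v]):
                continue
            nd = d + w
            if nd < dist[v] - tol:
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd, v))
            elif abs(nd - dist[v]) <= tol and pred[v] > u:
                pred[v] = u
    if not np.isfinite(dist[dst]):
        raise NoPathError(f"no path from {src} to {dst}")
    chain = [dst]
    while chain[-1] != src:
        chain.append(int(pred[chain[-1]]))
    chain.reverse()
    chain = np.asarray(chain)
    steps = np.linalg.norm(np.diff(mesh.vertex_coords[chain], axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    return GeodesicPath(chain, cum, ((labels[0], src), (labels[1], dst)))


def sample_along_path(surface_map: np.ndarray, path: GeodesicPath,
                      smoothing_k: float | None = None):
    """Values along the chain with cumulative distances.

    ``smoothing_k`` applies a centered sliding-window mean of window length
    ``round(k * chain length)`` (truncated at the ends), the local-k-point
    smoothing used to visualize gradients.
    """
    vals = np.asarray(surface_map, float)[path.vertex_chain]
    if smoothing_k:
        w = max(int(round(smoothing_k * len(path))), 1)
        vals = (pd.Series(vals).rolling(w, center=True, min_periods=1)
                .mean().to_numpy())
    return path.cumulative_distance.copy(), vals


def find_border_crossing(t_a: np.ndarray, t_b: np.ndarray,
                         path: GeodesicPath) -> int:
    """Vertex where the two t-value vectors cross along the path.

    ``t_a`` must dominate at the start (its finger's peak) and ``t_b`` at
    the end.  The first sign change of ``t_a - t_b`` is located and the
    bracketing chain vertex with the smaller absolute difference returned
    (ties to the earlier vertex).  Raises :class:`NoCrossingError` when the
    vectors never cross.
    """
    t_a = np.asarray(t_a, float)
    t_b = np.asarray(t_b, float)
    if t_a.shape != t_b.shape or len(t_a) != len(path):
        raise InvalidArgumentError("t vectors must match the chain length")
    if not (t_a[0] > t_b[0] and t_a[-1] < t_b[-1]):
        raise InvalidArgumentError("vectors not in peak-to-peak orientation")
    diff = t_a - t_b
    for i in range(len(diff) - 1):
        if diff[i] == 0:
            return int(path.vertex_chain[i])
        if diff[i] > 0 and diff[i + 1] <= 0:
            j = i if abs(diff[i]) <= abs(diff[i + 1]) else i + 1
            return int(path.vertex_chain[j])
    raise NoCrossingError("t-value vectors do not cross along the path")


def extract_gradient_samples(layer_maps: dict[str, np.ndarray],
                             path: GeodesicPath,
                             participant: str = "P01") -> pd.DataFrame:
    """Tidy table (participant, layer, normalized distance, value) along a path."""
    if path.length <= 0:
        raise InvalidArgumentError("gradient path has zero length")
    norm = path.cumulative_distance / path.length
    rows = []
    for layer, surface_map in layer_maps.items():
        vals = np.asarray(surface_map, float)[path.vertex_chain]
        for d, v in zip(norm, vals):
            rows.append((participant, layer, float(d), float(v)))
    return pd.DataFrame(rows, columns=["participant", "layer", "distance", "value"])


def corridor_paths(mesh: CorticalPatchMesh, seed_vertex: int,
                   inferior_y: float, superior_y: float, n_paths: int = 5,
                   tolerance: float | None = None,
                   spacing_factor: float = 2.0,
                   axis: str = "y") -> list[GeodesicPath]:
    """Equally spaced parallel geodesic paths through the seed region.

    Paths run from an inferior anchor (face proxy, ``inferior_y``) through
    the seed row to ``superior_y`` (the D2 peak axis).  Start/end points are
    offset along the anterior-posterior axis: the outermost paths sit
    ``spacing_factor`` vertex spacings either side of the seed, with
    ``n_paths`` equally spaced lines in between.  Sampled vertices are
    restricted to within ``tolerance`` (default one vertex spacing) of each
    path's axis line.  ``axis="x"`` transposes the roles of the two surface
    axes (fallback when the y-aligned sampling does not match the pattern).
    """
    if n_paths < 1:
        raise InvalidArgumentError("n_paths must be >= 1")
    s = mesh.surface_coords
    along, across = (1, 0) if axis == "y" else (0, 1)
    lo = min(inferior_y, superior_y)
    hi = max(inferior_y, superior_y)
    if not (s[:, along].min() - 1e-9 <= lo and hi <= s[:, along].max() + 1e-9):
        raise InvalidArgumentError("corridor endpoints outside the mesh")
    if tolerance is None:
        tolerance = mesh.vertex_spacing
    seed_across = s[seed_vertex, across]
    max_off = spacing_factor * mesh.vertex_spacing
    offsets = (np.linspace(-max_off, max_off, n_paths) if n_paths > 1
               else np.array([0.0]))
    paths = []
    for off in offsets:
        line = seed_across + off
        allowed = np.abs(s[:, across] - line) <= tolerance + 1e-9
        if not np.any(allowed):
            raise NoPathError("no vertices within tolerance of a corridor line")
        cand = np.flatnonzero(allowed)

        def _nearest(target_along):
            d = np.abs(s[cand, along] - target_along)
            return int(cand[np.argmin(d)])

        start = _nearest(inferior_y)
        end = _nearest(superior_y)
        paths.append(shortest_path(mesh, start, end, allowed=allowed,
                                   labels=("inferior", "superior")))
    return paths
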