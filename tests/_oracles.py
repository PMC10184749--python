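"""Independent oracles used to cross-check the package implementations.

Everything here is deliberately written from first principles — brute-force
enumeration, naive recursion, fixed-grid numeric integration — and shares no
code path with the implementations it validates.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import gammaln


# ---------------------------------------------------------------------------
# JZS Bayes factor: fixed-grid double integration of the JZS integrand.
# The noncentral-t density is built from its definition (normal numerator,
# scaled-chi denominator) rather than scipy.stats.nct.

def _nct_pdf_from_scratch(t: float, nu: int, lams: np.ndarray) -> np.ndarray:
    """Density of the noncentral t at ``t`` for an array of noncentralities.

    T = (Z + lam) / Y with Z ~ N(0,1) and Y = sqrt(chi2_nu / nu):
    f(t) = int_0^inf phi(t*y - lam) * y * f_Y(y) dy.
    """
    y = np.linspace(1e-6, 6.0, 1601)
    log_fy = (np.log(2.0) + (nu / 2.0) * np.log(nu / 2.0) - gammaln(nu / 2.0)
              + (nu - 1) * np.log(y) - nu * y ** 2 / 2.0)
    fy = np.exp(log_fy)
    z = t * y[:, None] - lams[None, :]
    phi = np.exp(-z ** 2 / 2.0) / np.sqrt(2 * np.pi)
    integrand = phi * (y * fy)[:, None]
    return np.trapezoid(integrand, y, axis=0)


def jzs_bf_oracle(t: float, n: int, r: float = 0.707,
                  side: str = "two-sided") -> float:
    """High-resolution fixed-grid JZS Bayes factor."""
    nu = n - 1
    # delta = r * tan(theta) maps the Cauchy prior to uniform on (-pi/2, pi/2)
    if side == "two-sided":
        theta = np.linspace(-np.pi / 2 + 1e-7, np.pi / 2 - 1e-7, 1601)
        scale = 1.0
    elif side in ("greater", "one-sided"):
        theta = np.linspace(1e-9, np.pi / 2 - 1e-7, 1601)
        scale = 2.0
    elif side == "less":
        theta = np.linspace(-np.pi / 2 + 1e-7, -1e-9, 1601)
        scale = 2.0
    else:
        raise ValueError(side)
    deltas = r * np.tan(theta)
    dens = _nct_pdf_from_scratch(t, nu, deltas * np.sqrt(n))
    m1 = scale * np.trapezoid(dens / np.pi, theta)
    m0 = _nct_pdf_from_scratch(t, nu, np.array([0.0]))[0]
    return float(m1 / m0)


# ---------------------------------------------------------------------------
# Shortest path: exhaustive search over simple paths with pruning.

def brute_force_shortest(coords: np.ndarray, edges: np.ndarray,
                         src: int, dst: int) -> float:
    """Minimal total edge length over all simple src->dst paths."""
    n = coords.shape[0]
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for a, b in edges:
        w = float(np.linalg.norm(coords[a] - coords[b]))
        adj[a].append((b, w))
        adj[b].append((a, w))
    best = [np.inf]
    visited = np.zeros(n, bool)

    def dfs(u, cost):
        if cost >= best[0]:
            return
        if u == dst:
            best[0] = cost
            return
        visited[u] = True
        for v, w in adj[u]:
            if not visited[v]:
                dfs(v, cost + w)
        visited[u] = False

    dfs(src, 0.0)
    return best[0]


# ---------------------------------------------------------------------------
# Discrete Fréchet distance: naive recursive definition with memoization.

def frechet_oracle(p: np.ndarray, q: np.ndarray) -> float:
    p = np.asarray(p, float)
    q = np.asarray(q, float)

    @lru_cache(maxsize=None)
    def c(i, j):
        d = float(np.linalg.norm(p[i] - q[j]))
        if i == 0 and j == 0:
            return d
        if i == 0:
            return max(c(0, j - 1), d)
        if j == 0:
            return max(c(i - 1, 0), d)
        return max(min(c(i - 1, j), c(i - 1, j - 1), c(i, j - 1)), d)

    return c(len(p) - 1, len(q) - 1)


# ---------------------------------------------------------------------------
# Equivolume placement: numeric shell-volume inversion.

def equivolume_oracle(inner_area: float, outer_area: float,
                      n_depths: int) -> np.ndarray:
    """Positions from the outer surface by fine-grained cumulative volume."""
    t = np.linspace(0.0, 1.0, 200001)
    area = outer_area + (inner_area - outer_area) * t
    vol = np.concatenate([[0.0], np.cumsum((area[1:] + area[:-1]) / 2.0)])
    vol /= vol[-1]
    targets = np.linspace(0.0, 1.0, n_depths)
    return np.interp(targets, vol, t)
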