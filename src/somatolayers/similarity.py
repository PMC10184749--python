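"""Similarity of finger-specific depth profiles via the discrete Fréchet distance.

Each finger's 21-depth profile becomes a 2-D polyline: the depth axis scaled
to [0, 1] and the quantitative value min-max scaled to [0, 1] using the
participant's pooled minimum/maximum across all five fingers for that
contrast (so between-finger shape differences, not absolute amplitude,
drive the distances).  The discrete Fréchet distance — the minimal leash
length needed to traverse both point sequences monotonically from start to
finish — is computed by dynamic programming over the coupling lattice with
Euclidean point distances; zero means perfectly aligned curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    FINGERS,
    NEIGHBOR_PAIRS,
    DegenerateDataError,
    InvalidArgumentError,
)


@dataclass
class SimilarityMatrix:
    labels: tuple[str, ...]
    distances: np.ndarray
    level: str = "participant"

    def pair(self, a: str, b: str) -> float:
        return float(self.distances[self.labels.index(a), self.labels.index(b)])


def normalize_profiles(profiles: dict[str, np.ndarray],
                       mode: str = "minmax") -> dict[str, np.ndarray]:
    """Turn per-finger depth profiles into commensurate 2-D curves.

    The value axis is scaled with the pooled min/max (or pooled mean/sd with
    ``mode="zscore"``) across the supplied fingers.
    """
    pool = np.concatenate([np.asarray(v, float) for v in profiles.values()])
    if np.ptp(pool) == 0:
        raise DegenerateDataError("profiles are constant across all fingers")
    out = {}
    for finger, vals in profiles.items():
        v = np.asarray(vals, float)
        depth = np.linspace(0.0, 1.0, v.size)
        if mode == "minmax":
            scaled = (v - pool.min()) / (pool.max() - pool.min())
        elif mode == "zscore":
            scaled = (v - pool.mean()) / pool.std(ddof=1)
        else:
            raise InvalidArgumentError(f"unknown normalization mode {mode!r}")
        out[finger] = np.column_stack([depth, scaled])
    return out


def normalize_profile(values: np.ndarray, vmin: float, vmax: float) -> np.ndarray:
    """Single-profile variant with an explicit pooled value range."""
    v = np.asarray(values, float)
    if vmax <= vmin:
        raise DegenerateDataError("degenerate value range")
    depth = np.linspace(0.0, 1.0, v.size)
    return np.column_stack([depth, (v - vmin) / (vmax - vmin)])


def discrete_frechet(p: np.ndarray, q: np.ndarray) -> float:
    """Discrete Fréchet distance between two point sequences.

    Dynamic programming over the coupling lattice:
    ``D[i, j] = max(d(p_i, q_j), min(D[i-1, j], D[i, j-1], D[i-1, j-1]))``.
    """
    p = np.atleast_2d(np.asarray(p, float))
    q = np.atleast_2d(np.asarray(q, float))
    if p.size == 0 or q.size == 0:
        raise InvalidArgumentError("curves must be non-empty")
    d = np.sqrt(((p[:, None, :] - q[None, :, :]) ** 2).sum(axis=2))
    n, m = d.shape
    ca = np.empty((n, m))
    ca[0, 0] = d[0, 0]
    for j in range(1, m):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, n):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
        for j in range(1, m):
            ca[i, j] = max(d[i, j], min(ca[i - 1, j], ca[i, j - 1],
                                        ca[i - 1, j - 1]))
    return float(ca[-1, -1])


def similarity_matrices(cohort_profiles: dict[str, dict[str, np.ndarray]],
                        mode: str = "minmax"):
    """Per-participant and group-average Fréchet similarity matrices.

    ``cohort_profiles`` maps participant label -> finger -> 21-value profile.
    Participants missing any of the five fingers are excluded (and listed in
    the returned ``excluded``).  Also returns a tidy neighboring-pair table
    (participant, pair, distance) ready for the trimmed-means ANOVA.
    """
    individual: dict[str, SimilarityMatrix] = {}
    excluded: list[str] = []
    rows = []
    for pid, profs in cohort_profiles.items():
        if any(f not in profs for f in FINGERS):
            excluded.append(pid)
            continue
        curves = normalize_profiles({f: profs[f] for f in FINGERS}, mode=mode)
        m = np.zeros((5, 5))
        for i in range(5):
            for j in range(i + 1, 5):
                m[i, j] = m[j, i] = discrete_frechet(curves[FINGERS[i]],
                                                     curves[FINGERS[j]])
        individual[pid] = SimilarityMatrix(FINGERS, m, level="participant")
        for a, b in NEIGHBOR_PAIRS:
            rows.append((pid, f"{a}-{b}", individual[pid].pair(a, b)))
    if not individual:
        raise InvalidArgumentError("no participant has all five fingers")
    group = SimilarityMatrix(
        FINGERS,
        np.mean([sm.distances for sm in individual.values()], axis=0),
        level="group-average")
    pairs = pd.DataFrame(rows, columns=["participant", "pair", "distance"])
    return individual, group, pairs, excluded
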