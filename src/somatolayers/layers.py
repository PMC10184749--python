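"""Cortical depth profiles and layer-compartment definitions.

Depth profiles carry 21 samples from the CSF side (depth 1) to the white
matter side (depth 21).  Two compartment schemes are supported:

* **anatomical** — data driven: the two deepest (plateau) depths are
  excluded, and the middle compartment is delimited by the first minimum and
  first maximum of the first derivative of the group qT1 profile (the
  signature of the heavily myelinated Bands of Baillarger).  On the
  calibrated canonical profile this yields outer/middle/inner sizes 4/7/8.
* **equally spaced** — the three most superficial and two deepest depths are
  removed (partial-volume control) and the remaining 16 are split into four
  compartments of four (superficial, outer middle, inner middle, deep).

Derivatives are central differences between neighboring sampling points
(one-sided at the ends); extrema of the first derivative are located at the
zero crossings of the second derivative, linearly interpolated and snapped
to the nearest sampling depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    ANATOMICAL_LAYERS,
    EQUALLY_SPACED_LAYERS,
    N_DEPTHS,
    DegenerateDataError,
    InvalidArgumentError,
    NoExtremaError,
)

_VALID_SIGNS = {"qT1": (0.0, None), "nQSM": (None, 0.0),
                "pQSM": (0.0, None), "aQSM": (0.0, None)}


@dataclass
class QuantitativeProfile:
    """A 21-depth quantitative profile for one contrast."""

    contrast: str
    values: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.shape != (N_DEPTHS,):
            raise InvalidArgumentError(f"expected {N_DEPTHS} depth samples")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("profile contains non-finite values")


@dataclass
class LayerCompartments:
    """Mapping from depth index (1-based) to compartment label."""

    scheme: str
    assignments: dict[int, str]
    excluded: tuple[int, ...]

    def depths(self, label: str) -> list[int]:
        return [d for d, lab in sorted(self.assignments.items()) if lab == label]

    @property
    def labels(self) -> tuple[str, ...]:
        return (ANATOMICAL_LAYERS if self.scheme == "anatomical"
                else EQUALLY_SPACED_LAYERS)

    def sizes(self) -> tuple[int, ...]:
        return tuple(len(self.depths(lab)) for lab in self.labels)


# ---------------------------------------------------------------------------
# Profile extraction

def roi_depth_profile(depth_map: np.ndarray, roi: np.ndarray,
                      contrast: str = "qT1", provenance: str = "") -> QuantitativeProfile:
    """Mean profile over the ROI vertices of a (V, 21) depth-sampled map."""
    roi = np.asarray(roi, int)
    if roi.size == 0:
        raise InvalidArgumentError("empty ROI")
    if roi.min() < 0 or roi.max() >= depth_map.shape[0]:
        raise InvalidArgumentError("ROI index out of range")
    return QuantitativeProfile(contrast=contrast,
                               values=depth_map[roi].mean(axis=0),
                               provenance=provenance)


# ---------------------------------------------------------------------------
# Derivative structure

def central_difference(values: np.ndarray) -> np.ndarray:
    """Central difference between two neighboring samples; one-sided ends."""
    v = np.asarray(values, float)
    d = np.empty_like(v)
    d[1:-1] = (v[2:] - v[:-2]) / 2.0
    d[0] = v[1] - v[0]
    d[-1] = v[-1] - v[-2]
    return d


def derivative_extrema(profile: QuantitativeProfile | np.ndarray,
                       prominence_frac: float = 0.15):
    """First/second derivative and extrema of the first derivative.

    Extrema are zero locations of the second derivative: each sign change is
    linearly interpolated and snapped to the nearest sampling index
    (0-based), classified min/max by the local sign change (the third
    difference).  Crossings in the two boundary intervals are not trusted
    (their second derivative rests on one-sided differences) and adjacent
    extremum pairs whose first-derivative prominence is below
    ``prominence_frac`` of the first-derivative range are pruned as noise.
    """
    values = profile.values if isinstance(profile, QuantitativeProfile) else np.asarray(profile, float)
    if values.size < 5:
        raise InvalidArgumentError("need at least 5 depth samples")
    d1 = central_difference(values)
    d2 = central_difference(d1)
    out: list[list] = []
    for i in range(1, len(d2) - 2):
        a, b = d2[i], d2[i + 1]
        if a * b < 0:
            z = i + a / (a - b)
            out.append([int(round(z)), "min" if a < 0 else "max"])
        elif a == 0 and b != 0 and d2[i - 1] * b < 0:
            out.append([i, "min" if b > 0 else "max"])
    tol = prominence_frac * (d1.max() - d1.min())
    while len(out) >= 2:
        proms = [abs(d1[out[j + 1][0]] - d1[out[j][0]]) for j in range(len(out) - 1)]
        j = int(np.argmin(proms))
        if proms[j] < tol:
            del out[j:j + 2]
        else:
            break
    return d1, d2, [(pos, kind) for pos, kind in out]


# ---------------------------------------------------------------------------
# Compartment schemes

def define_anatomical_compartments(profile: QuantitativeProfile | np.ndarray,
                                   n_plateau: int = 2) -> LayerCompartments:
    """Outer/middle/inner compartments from first-derivative extrema.

    The ``n_plateau`` deepest depths (where qT1 stabilizes) are excluded.
    The first-minimum depth is the last outer depth and the first-maximum
    depth is the last middle depth; remaining retained depths below form the
    inner compartment.
    """
    values = profile.values if isinstance(profile, QuantitativeProfile) else np.asarray(profile, float)
    n = values.size
    _, _, ex = derivative_extrema(values)
    if len(ex) < 2 or ex[0][1] != "min" or ex[1][1] != "max":
        raise NoExtremaError("first derivative lacks a minimum-then-maximum pair")
    first_min = ex[0][0] + 1   # 1-based depths
    first_max = ex[1][0] + 1
    retained_last = n - n_plateau
    if not (1 <= first_min < first_max <= retained_last):
        raise NoExtremaError("extrema positions incompatible with layering")
    assignments = {}
    for d in range(1, retained_last + 1):
        if d <= first_min:
            assignments[d] = "outer"
        elif d <= first_max:
            assignments[d] = "middle"
        else:
            assignments[d] = "inner"
    excluded = tuple(range(retained_last + 1, n + 1))
    return LayerCompartments("anatomical", assignments, excluded)


def define_equally_spaced_compartments(n_depths: int = N_DEPTHS) -> LayerCompartments:
    """Four equal compartments after dropping 3 superficial + 2 deep depths."""
    if n_depths != N_DEPTHS:
        raise InvalidArgumentError("equally spaced scheme requires 21 depths")
    retained = list(range(4, 20))  # depths 4..19 inclusive, 16 depths
    assignments = {d: EQUALLY_SPACED_LAYERS[i // 4]
                   for i, d in enumerate(retained)}
    excluded = (1, 2, 3, 20, 21)
    return LayerCompartments("equally_spaced", assignments, excluded)


def compartment_average(depth_map: np.ndarray,
                        comp: LayerCompartments) -> dict[str, np.ndarray]:
    """Per-compartment surface maps: mean over each compartment's depths."""
    if depth_map.shape[1] < max(comp.assignments):
        raise InvalidArgumentError("map has fewer depths than the scheme")
    out = {}
    for label in comp.labels:
        idx = [d - 1 for d in comp.depths(label)]
        out[label] = depth_map[:, idx].mean(axis=1)
    return out


def functional_depth_average(depth_map: np.ndarray,
                             min_relative_depth: float = 0.2) -> np.ndarray:
    """Mean over depths at relative depth >= 20% (superficial-vein control).

    For 21 depths this drops the 4 most superficial samples and averages
    depths 5..21.
    """
    n = depth_map.shape[1]
    if n < 5:
        raise InvalidArgumentError("need at least 5 depth samples")
    # sample i (0-based) sits at relative depth i / (n - 1); the boundary
    # sample at exactly 20% is retained
    first = int(np.ceil(min_relative_depth * (n - 1) - 1e-12))
    return depth_map[:, first:].mean(axis=1)


# ---------------------------------------------------------------------------
# Equivolume depth placement

def equivolume_fractions(thickness: float, inner_area: float, outer_area: float,
                         n_depths: int = N_DEPTHS) -> np.ndarray:
    """Depth positions (fractions from the outer surface) enclosing equal volume.

    The local cortical ribbon is modelled with surface area varying linearly
    from ``outer_area`` (CSF side) to ``inner_area`` (WM side); each of the
    ``n_depths - 1`` shells between successive positions encloses the same
    tissue volume.  With equal areas this reduces to equidistant spacing.
    Positions are fractions of ``thickness`` measured from the outer surface
    (consistent with depth 1 = CSF side).
    """
    if inner_area <= 0 or outer_area <= 0:
        raise InvalidArgumentError("areas must be positive")
    if n_depths < 2:
        raise InvalidArgumentError("need at least 2 depth positions")
    f = np.linspace(0.0, 1.0, n_depths)   # cumulative volume fractions
    a0, a1 = float(outer_area), float(inner_area)
    if np.isclose(a0, a1):
        return f
    # area(t) = a0 + (a1-a0) t with t from outer; cumulative volume
    # V(t)/V(1) = (a0 t + (a1-a0) t^2/2) / ((a0+a1)/2); invert the quadratic
    da = a1 - a0
    disc = a0 ** 2 + da * (a0 + a1) * f
    t = (np.sqrt(disc) - a0) / da
    return t
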