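"""Shared containers and constants for the somatotopic-layer analysis suite.

The sensory space is the 1-D inferior-to-superior finger axis used for
population receptive field (pRF) modelling: it spans ±12.5 units, each of
the five fingers (D1..D5, thumb to little finger) occupying 5 units, so the
finger centers sit at -10, -5, 0, +5, +10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# ---------------------------------------------------------------------------
# Sensory-axis constants

FINGERS: tuple[str, ...] = ("D1", "D2", "D3", "D4", "D5")
SENSORY_HALFSPAN: float = 12.5
FINGER_SPAN: float = 5.0
FINGER_CENTERS: dict[str, float] = {
    f: -SENSORY_HALFSPAN + (i + 0.5) * FINGER_SPAN for i, f in enumerate(FINGERS)
}
#: pRF width bounds: 1/10 of one finger's span up to the whole hand (25 units).
SIGMA_MIN: float = FINGER_SPAN / 10.0
SIGMA_MAX: float = 5 * FINGER_SPAN

N_DEPTHS: int = 21
CONTRASTS: tuple[str, ...] = ("qT1", "nQSM", "pQSM", "aQSM")

NEIGHBOR_PAIRS: tuple[tuple[str, str], ...] = (
    ("D1", "D2"), ("D2", "D3"), ("D3", "D4"), ("D4", "D5"))

ANATOMICAL_LAYERS: tuple[str, ...] = ("outer", "middle", "inner")
EQUALLY_SPACED_LAYERS: tuple[str, ...] = (
    "superficial", "outer_middle", "inner_middle", "deep")


# ---------------------------------------------------------------------------
# Errors

class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class NoExtremaError(RuntimeError):
    """A profile lacks the derivative extrema needed for anatomical layering."""


class NoCrossingError(RuntimeError):
    """Two t-value vectors never cross along the sampled path."""


class NoPathError(RuntimeError):
    """Requested mesh vertices are not connected."""


class DegenerateDataError(ValueError):
    """Input data carry no variance where variance is required."""


# ---------------------------------------------------------------------------
# Mesh container

@dataclass
class CorticalPatchMesh:
    """Triangulated cortical patch.

    ``vertex_coords`` are 3-D embedding coordinates in mm.  ``surface_coords``
    are the 2-D intrinsic (flattened) coordinates: column 0 runs along the
    anterior-posterior x axis, column 1 along the inferior-superior y axis.
    For a bent patch the intrinsic coordinates are preserved, so finger bands
    and corridor axes remain well defined while geodesic and chord distances
    differ.
    """

    vertex_coords: np.ndarray
    triangles: np.ndarray
    vertex_spacing: float
    axis_frame: np.ndarray
    surface_coords: np.ndarray
    rows: int = 0
    cols: int = 0
    _edges: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_vertices(self) -> int:
        return int(self.vertex_coords.shape[0])

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) int array."""
        if self._edges is None:
            t = self.triangles
            e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [0, 2]]])
            e = np.sort(e, axis=1)
            self._edges = np.unique(e, axis=0)
        return self._edges

    @property
    def edge_lengths(self) -> np.ndarray:
        e = self.edges
        d = self.vertex_coords[e[:, 0]] - self.vertex_coords[e[:, 1]]
        return np.linalg.norm(d, axis=1)

    def validate(self) -> None:
        t = self.triangles
        if t.min() < 0 or t.max() >= self.n_vertices:
            raise InvalidArgumentError("triangle references invalid vertex index")
        if np.any(self.edge_lengths <= 0):
            raise InvalidArgumentError("zero-length mesh edge")


@dataclass
class FingerTopography:
    """Per-vertex pRF estimates and winner-takes-all finger labels.

    ``prf_center`` is the pRF center x on the ±12.5-unit sensory axis;
    ``prf_width`` the Gaussian SD sigma; both are NaN for unassigned
    vertices.  ``finger_label`` holds indices into :data:`FINGERS`
    (-1 = unassigned).  ``peak_vertices`` maps finger name -> vertex index of
    the maximum t value inside that finger's ROI.
    """

    prf_center: np.ndarray
    prf_width: np.ndarray
    explained_variance: np.ndarray
    model_confidence: np.ndarray
    finger_label: np.ndarray
    peak_vertices: dict[str, int] = field(default_factory=dict)

    @property
    def n_vertices(self) -> int:
        return int(self.prf_center.shape[0])

    def roi(self, finger: str) -> np.ndarray:
        """Vertex indices labelled as ``finger``."""
        idx = FINGERS.index(finger)
        return np.flatnonzero(self.finger_label == idx)

    def hand_roi(self) -> np.ndarray:
        return np.flatnonzero(self.finger_label >= 0)


@dataclass
class BoldTimeSeries:
    """Per-vertex BOLD signal, arbitrary units; one row per vertex."""

    values: np.ndarray
    TR: float

    @property
    def n_volumes(self) -> int:
        return int(self.values.shape[1])
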