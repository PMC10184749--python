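"""Synthetic cortical patches with known laminar and somatotopic ground truth.

This module generates everything the analysis pipeline consumes: a
triangulated cortical patch standing in for the BA 3b hand region, per-vertex
quantitative maps sampled at 21 intracortical depths (qT1 in ms; nQSM, pQSM
and aQSM in ppm), tactile stimulation designs (phase-encoded and blocked),
and BOLD time series driven by a 1-D Gaussian pRF model.  Ground truth —
finger band locations, injected low-myelin septa, linear structural
gradients, a hand-versus-face contrast — is explicit, so every downstream
stage can be validated against what was put in.

The canonical qT1 depth profile is calibrated so that the derivative-based
anatomical layering of :mod:`somatolayers.layers` recovers an outer/middle/
inner split of 4/7/8 depths (with the two deepest plateau depths excluded),
and so that the three compartment means sit close to 2105, 1884 and 1658 ms.
The profile decreases from the CSF side toward white matter with a localized
dip-and-recovery around depths 9-12 emulating the heavily myelinated outer
Band of Baillarger.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    CONTRASTS,
    FINGER_CENTERS,
    FINGER_SPAN,
    FINGERS,
    N_DEPTHS,
    BoldTimeSeries,
    CorticalPatchMesh,
    FingerTopography,
    InvalidArgumentError,
)

# ---------------------------------------------------------------------------
# Canonical depth profiles (depth 1 = CSF side, depth 21 = WM side)

#: Calibrated canonical qT1 profile (ms).  See module docstring.
CANONICAL_QT1 = np.array([
    2160.0, 2146.5, 2115.0, 2040.4, 1963.0, 1914.8, 1881.4, 1848.0,
    1814.7, 1801.7, 1818.8, 1835.9, 1820.9, 1773.0, 1703.8, 1633.7,
    1575.0, 1521.2, 1495.7, 1495.7, 1495.7,
])

#: nQSM (ppm): u-shaped, everywhere <= 0, closest to zero at mid-depth with a
#: small plateau where layer IV is expected.
CANONICAL_NQSM = np.array([
    -0.0125, -0.0122, -0.0116, -0.0108, -0.0099, -0.0090, -0.0082, -0.0076,
    -0.0072, -0.0070, -0.0072, -0.0075, -0.0080, -0.0086, -0.0092, -0.0097,
    -0.0101, -0.0104, -0.0106, -0.0107, -0.0107,
])

#: pQSM (ppm): top-hat plateau with an upper peak at depth 8 (middle
#: compartment, layer IV) and a lower peak at depth 15 (inner compartment).
CANONICAL_PQSM = np.array([
    0.0045, 0.0055, 0.0068, 0.0080, 0.0090, 0.0097, 0.0104, 0.0110,
    0.0104, 0.0098, 0.0095, 0.0094, 0.0096, 0.0100, 0.0105, 0.0100,
    0.0094, 0.0088, 0.0082, 0.0076, 0.0070,
])

#: aQSM (ppm): overall mineralization, decreasing from outer to inner depths.
CANONICAL_AQSM = np.array([
    0.0120, 0.0118, 0.0115, 0.0112, 0.0109, 0.0106, 0.0103, 0.0101,
    0.0099, 0.0097, 0.0096, 0.0094, 0.0092, 0.0090, 0.0088, 0.0086,
    0.0084, 0.0083, 0.0082, 0.0081, 0.0080,
])

_CANONICAL = {
    "qT1": CANONICAL_QT1,
    "nQSM": CANONICAL_NQSM,
    "pQSM": CANONICAL_PQSM,
    "aQSM": CANONICAL_AQSM,
}

#: Depth weighting of septa injection: maximal in the middle compartment
#: (centered on depth 8) but non-zero at all depths.
SEPTA_DEPTH_WEIGHT = 0.4 + 0.6 * np.exp(
    -((np.arange(1, N_DEPTHS + 1) - 8.0) ** 2) / (2 * 3.5 ** 2))

#: Default per-contrast measurement noise (sd per vertex and depth).
DEFAULT_NOISE_SD = {"qT1": 60.0, "nQSM": 0.002, "pQSM": 0.002, "aQSM": 0.002}

#: Per-compartment face-minus-hand offsets used for the body-part contrast,
#: keyed by contrast; tuples are (outer, middle, inner).  The face shows
#: lower qT1 (more myelin) in outer and inner compartments and lower
#: iron/mineralization.
DEFAULT_BODYPART_OFFSETS = {
    "qT1": (-30.0, 0.0, -37.0),
    "nQSM": (0.0, 0.0, 0.0),
    "pQSM": (-0.002, -0.002, -0.002),
    "aQSM": (-0.001, -0.001, -0.001),
}


def canonical_depth_profile(contrast: str, params: dict | None = None) -> np.ndarray:
    """Return the canonical 21-depth profile for ``contrast``.

    ``params`` may override ``amplitude_scale`` (multiplies deviations from
    the profile mean, preserving the mean level) and ``offset`` (additive).
    """
    if contrast not in _CANONICAL:
        raise InvalidArgumentError(f"unknown contrast {contrast!r}")
    prof = _CANONICAL[contrast].copy()
    if params:
        scale = params.get("amplitude_scale", 1.0)
        if scale != 1.0:
            m = prof.mean()
            prof = m + scale * (prof - m)
        prof = prof + params.get("offset", 0.0)
    return prof


# ---------------------------------------------------------------------------
# Mesh generation

def build_patch_mesh(rows: int, cols: int, spacing: float,
                     curvature: float | None = None) -> CorticalPatchMesh:
    """Regular triangulated grid of ``rows`` x ``cols`` vertices.

    Rows advance along the inferior-to-superior (y) axis, columns along the
    anterior-to-posterior (x) axis.  With ``curvature`` set, the sheet is
    bent cylindrically around the y axis with the given bend radius (mm), so
    geodesic distances exceed straight-line chord distances.
    """
    if rows < 2 or cols < 2 or spacing <= 0:
        raise InvalidArgumentError("rows, cols >= 2 and spacing > 0 required")
    if curvature is not None and curvature <= 0:
        raise InvalidArgumentError("bend radius must be positive")

    jj, ii = np.meshgrid(np.arange(cols), np.arange(rows))
    x = jj.ravel() * spacing
    y = ii.ravel() * spacing
    surface = np.column_stack([x, y])
    if curvature is None:
        coords = np.column_stack([x, y, np.zeros_like(x)])
    else:
        r = float(curvature)
        coords = np.column_stack([r * np.sin(x / r), y, r * (1 - np.cos(x / r))])

    # two triangles per grid cell with checkerboard-alternating diagonals
    # (the symmetric triangulation: no global diagonal bias)
    idx = np.arange(rows * cols).reshape(rows, cols)
    a = idx[:-1, :-1].ravel()
    b = idx[:-1, 1:].ravel()
    c = idx[1:, :-1].ravel()
    d = idx[1:, 1:].ravel()
    ii2, jj2 = np.meshgrid(np.arange(rows - 1), np.arange(cols - 1),
                           indexing="ij")
    even = (ii2 % 2 == 0).ravel()   # alternate diagonal orientation per row
    t1 = np.where(even[:, None], np.column_stack([a, b, d]),
                  np.column_stack([a, b, c]))
    t2 = np.where(even[:, None], np.column_stack([a, d, c]),
                  np.column_stack([b, d, c]))
    tris = np.concatenate([t1, t2])

    axis_frame = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    mesh = CorticalPatchMesh(
        vertex_coords=coords, triangles=tris, vertex_spacing=float(spacing),
        axis_frame=axis_frame, surface_coords=surface, rows=rows, cols=cols)
    mesh.validate()
    return mesh


def nearest_vertex(mesh: CorticalPatchMesh, x: float, y: float) -> int:
    """Vertex index closest to intrinsic surface coordinates (x, y)."""
    d = mesh.surface_coords - np.array([x, y])
    return int(np.argmin(np.einsum("ij,ij->i", d, d)))


# ---------------------------------------------------------------------------
# Ground truth

@dataclass
class Septum:
    """A low-myelin border injected between two neighboring fingers.

    ``border`` identifies the finger pair (e.g. ``"D2-D3"``) or the special
    value ``"face-hand"`` for the boundary between the face subregion and D1.
    ``elevation`` is the qT1 increase in ms at the septum center (low myelin
    = high qT1); ``width`` the Gaussian cross-section sd in mm.
    """

    border: str
    elevation: float
    width: float = 0.5

    def __post_init__(self):
        if self.elevation < 0:
            raise InvalidArgumentError("septum elevation must be >= 0")


@dataclass
class GroundTruthSpec:
    """Generative parameters for one synthetic participant."""

    finger_band_centers: np.ndarray
    band_width: float
    septa: list[Septum] = field(default_factory=list)
    gradient_slope_qt1: float = 0.0
    gradient_slope_qsm: float = 0.0
    bodypart_offsets: dict | None = None
    face_center_y: float | None = None
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    amplitude_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.finger_band_centers = np.asarray(self.finger_band_centers, float)
        if self.finger_band_centers.shape != (5,):
            raise InvalidArgumentError("five finger band centers required")
        if np.any(np.diff(self.finger_band_centers) <= 0):
            raise InvalidArgumentError("band centers must increase along y")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise InvalidArgumentError("noise sd must be >= 0")


def default_truth(mesh: CorticalPatchMesh, *, with_face: bool = False,
                  seed: int = 0, **overrides) -> GroundTruthSpec:
    """Ground truth with five contiguous finger bands filling the patch.

    Bands are laid out inferior to superior (D1 lowest).  With ``with_face``
    the bands occupy the superior part of the patch and a face subregion is
    placed 10 mm inferior to the D1 band center; the mesh must be tall
    enough (>= 5 bands + 10 mm).
    """
    y_max = mesh.surface_coords[:, 1].max()
    if with_face:
        span = y_max - 10.0
        if span <= 0:
            raise InvalidArgumentError("patch too short for a face subregion")
        width = overrides.pop("band_width", span / 5.0)
        first = 10.0 + width / 2.0
    else:
        width = overrides.pop("band_width", (y_max / 5.0))
        first = width / 2.0
    centers = first + width * np.arange(5)
    if centers[-1] + width / 2.0 > y_max + 1e-9:
        raise InvalidArgumentError("finger bands do not fit inside the patch")
    face_y = centers[0] - 10.0 if with_face else None
    bodypart = dict(DEFAULT_BODYPART_OFFSETS) if with_face else None
    defaults = dict(finger_band_centers=centers, band_width=width,
                    face_center_y=face_y, bodypart_offsets=bodypart, seed=seed)
    defaults.update(overrides)
    return GroundTruthSpec(**defaults)


@dataclass
class Participant:
    """One synthetic participant: maps plus ground-truth topography."""

    mesh: CorticalPatchMesh
    maps: dict[str, np.ndarray]
    topography: FingerTopography
    truth: GroundTruthSpec
    face_vertices: np.ndarray | None = None
    label: str = "P01"


def _band_positions(truth: GroundTruthSpec):
    """Border y positions between neighboring bands (4 values)."""
    c = truth.finger_band_centers
    return (c[:-1] + c[1:]) / 2.0


def normalized_span_position(truth: GroundTruthSpec, y: np.ndarray) -> np.ndarray:
    """y mapped to [0, 1] over the D1-center..D5-center span.

    This is the normalization used for injected linear gradients, matching
    the normalized geodesic distance of a D1-to-D5 path.
    """
    c = truth.finger_band_centers
    return (np.asarray(y, float) - c[0]) / (c[4] - c[0])


def septum_field(mesh: CorticalPatchMesh, truth: GroundTruthSpec) -> np.ndarray:
    """Per-vertex x per-depth qT1 elevation from all injected septa (ms)."""
    y = mesh.surface_coords[:, 1]
    field = np.zeros((mesh.n_vertices, N_DEPTHS))
    borders = _band_positions(truth)
    names = [f"{a}-{b}" for a, b in zip(FINGERS[:-1], FINGERS[1:])]
    for s in truth.septa:
        if s.border == "face-hand":
            if truth.face_center_y is None:
                raise InvalidArgumentError("face-hand septum without face region")
            y0 = (truth.face_center_y + truth.finger_band_centers[0]) / 2.0
        else:
            try:
                y0 = borders[names.index(s.border)]
            except ValueError:
                raise InvalidArgumentError(f"unknown border {s.border!r}") from None
        cross = s.elevation * np.exp(-((y - y0) ** 2) / (2 * s.width ** 2))
        # accumulate per-septum products so injection is exactly additive
        field += cross[:, None] * SEPTA_DEPTH_WEIGHT[None, :]
    return field


def _face_mask(mesh: CorticalPatchMesh, truth: GroundTruthSpec) -> np.ndarray | None:
    if truth.face_center_y is None:
        return None
    y = mesh.surface_coords[:, 1]
    return np.abs(y - truth.face_center_y) <= truth.band_width / 2.0


# anatomical depth membership used for layer-dependent body-part offsets
_DEPTH_COMPARTMENT = np.array([0] * 4 + [1] * 7 + [2] * 10)  # outer/middle/inner+plateau


def synthesize_participant(mesh: CorticalPatchMesh, truth: GroundTruthSpec,
                           label: str = "P01") -> Participant:
    """Generate per-contrast depth-sampled maps plus ground-truth topography.

    The generative model is additive: canonical profile (amplitude-scaled per
    participant) + septa elevation (qT1 only) + linear inferior-to-superior
    gradient + body-part offset + i.i.d. Gaussian noise.
    """
    y = mesh.surface_coords[:, 1]
    c = truth.finger_band_centers
    if c[0] - truth.band_width / 2 < -1e-9 or \
            c[-1] + truth.band_width / 2 > y.max() + 1e-9:
        raise InvalidArgumentError("finger bands outside the patch")

    rng = np.random.default_rng(truth.seed)
    grad_pos = normalized_span_position(truth, y)
    septa = septum_field(mesh, truth) if truth.septa else None
    face = _face_mask(mesh, truth)

    maps: dict[str, np.ndarray] = {}
    for contrast in CONTRASTS:
        prof = canonical_depth_profile(
            contrast, {"amplitude_scale": truth.amplitude_scale})
        m = np.broadcast_to(prof, (mesh.n_vertices, N_DEPTHS)).copy()
        slope = (truth.gradient_slope_qt1 if contrast == "qT1"
                 else truth.gradient_slope_qsm)
        if slope:
            m += slope * grad_pos[:, None]
        if contrast == "qT1" and septa is not None:
            m += septa
        if face is not None and truth.bodypart_offsets:
            offs = truth.bodypart_offsets.get(contrast)
            if offs is not None:
                m[face] += np.asarray(offs, float)[_DEPTH_COMPARTMENT][None, :]
        sd = truth.noise_sd.get(contrast, 0.0)
        if sd > 0:
            m = m + rng.normal(0.0, sd, m.shape)
        maps[contrast] = m

    # ground-truth topography: continuous somatotopy within each band
    half = truth.band_width / 2.0
    centers_x = np.array([FINGER_CENTERS[f] for f in FINGERS])
    label_idx = np.full(mesh.n_vertices, -1, dtype=int)
    x_true = np.full(mesh.n_vertices, np.nan)
    for i in range(5):
        in_band = np.abs(y - c[i]) <= half + 1e-9
        label_idx[in_band] = i
        x_true[in_band] = centers_x[i] + FINGER_SPAN * (y[in_band] - c[i]) / truth.band_width
    topo = FingerTopography(
        prf_center=x_true,
        prf_width=np.where(label_idx >= 0, 2.0, np.nan),
        explained_variance=np.where(label_idx >= 0, 1.0, 0.0),
        model_confidence=np.where(label_idx >= 0, 1.0, 0.0),
        finger_label=label_idx,
    )
    return Participant(mesh=mesh, maps=maps, topography=topo, truth=truth,
                       face_vertices=None if face is None else np.flatnonzero(face),
                       label=label)


# ---------------------------------------------------------------------------
# Stimulation designs

@dataclass
class StimulusDesign:
    """Timing of one tactile stimulation run."""

    design_kind: str
    TR: float
    n_volumes: int
    cycle_duration: float
    per_finger_duration: float
    n_cycles: int
    direction: str
    gap_schedule: list[tuple[float, str]]
    finger_onsets: list[tuple[float, float, str]]

    @property
    def duration(self) -> float:
        return self.n_volumes * self.TR


def generate_design(kind: str = "phase_encoded", *, TR: float = 2.0,
                    per_finger_duration: float = 5.12, n_cycles: int = 20,
                    direction: str = "forward", n_gaps_per_finger: int = 3,
                    gap_duration: float = 0.18,
                    stimulations_per_finger: int = 10,
                    pause_short: float = 2.0, pause_long: float = 6.0,
                    long_pause_fraction: float = 0.3,
                    seed: int = 0) -> StimulusDesign:
    """Build a phase-encoded or blocked stimulation design.

    Phase-encoded defaults reproduce the canonical protocol: 20 cycles of
    25.6 s (each finger once for 5.12 s per cycle), TR 2 s, 256 volumes,
    3 attention gaps per finger (15 per run) placed randomly without overlap.
    Blocked defaults: 10 stimulations per finger in pseudorandom order (no
    finger more than twice in a row), pauses of 2 s (70%) or 6 s (30%)
    counterbalanced across fingers.
    """
    rng = np.random.default_rng(seed)
    if per_finger_duration <= 0 or n_cycles < 1:
        raise InvalidArgumentError("per_finger_duration > 0 and n_cycles >= 1")

    if kind == "phase_encoded":
        cycle = 5 * per_finger_duration
        total = n_cycles * cycle
        n_vol = total / TR
        if abs(n_vol - round(n_vol)) > 1e-9:
            raise InvalidArgumentError("design duration not divisible into volumes")
        order = list(FINGERS) if direction == "forward" else list(FINGERS)[::-1]
        onsets = [(ci * cycle + k * per_finger_duration, per_finger_duration, f)
                  for ci in range(n_cycles) for k, f in enumerate(order)]
        # gaps: n per finger, each inside one of that finger's epochs,
        # at most one gap per epoch
        gaps: list[tuple[float, str]] = []
        for f in FINGERS:
            epochs = [o for o in onsets if o[2] == f]
            chosen = rng.choice(len(epochs), size=n_gaps_per_finger, replace=False)
            for ci in chosen:
                onset, dur, _ = epochs[ci]
                t = onset + rng.uniform(0.0, dur - gap_duration)
                gaps.append((float(t), f))
        gaps.sort()
        return StimulusDesign(
            design_kind="phase_encoded", TR=TR, n_volumes=int(round(n_vol)),
            cycle_duration=cycle, per_finger_duration=per_finger_duration,
            n_cycles=n_cycles, direction=direction, gap_schedule=gaps,
            finger_onsets=onsets)

    if kind == "blocked":
        n_stim = stimulations_per_finger
        # pseudorandom order, no finger more than twice in a row
        while True:
            seq = rng.permutation(np.repeat(np.arange(5), n_stim))
            ok = all(not (seq[i] == seq[i - 1] == seq[i - 2])
                     for i in range(2, len(seq)))
            if ok:
                break
        # pauses counterbalanced: each finger gets the same long/short mix
        n_long = int(round(long_pause_fraction * n_stim))
        pause_pool = {i: rng.permutation([pause_long] * n_long +
                                         [pause_short] * (n_stim - n_long)).tolist()
                      for i in range(5)}
        onsets = []
        t = 0.0
        for fi in seq:
            onsets.append((t, per_finger_duration, FINGERS[fi]))
            t += per_finger_duration + pause_pool[fi].pop()
        n_vol = int(np.ceil(t / TR))
        return StimulusDesign(
            design_kind="blocked", TR=TR, n_volumes=n_vol,
            cycle_duration=0.0, per_finger_duration=per_finger_duration,
            n_cycles=0, direction="n/a", gap_schedule=[], finger_onsets=onsets)

    raise InvalidArgumentError(f"unknown design kind {kind!r}")


# ---------------------------------------------------------------------------
# Hemodynamics

DEFAULT_HRF = {"peak": 6.0, "undershoot": 16.0, "ratio": 6.0}
_DT = 0.04  # fine time grid (s); 5.12 s and 2 s are both integer multiples


def double_gamma_hrf(t: np.ndarray, peak: float = 6.0, undershoot: float = 16.0,
                     ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak normalized to 1."""
    from scipy.stats import gamma as gamma_dist
    h = gamma_dist.pdf(t, peak) - gamma_dist.pdf(t, undershoot) / ratio
    return h / h.max()


def finger_regressors(design: StimulusDesign, hrf: dict | None = None,
                      include_gaps: bool = True) -> np.ndarray:
    """(n_volumes, 5) matrix of per-finger boxcars convolved with the HRF."""
    hrf = {**DEFAULT_HRF, **(hrf or {})}
    n_fine = int(round(design.duration / _DT))
    box = np.zeros((5, n_fine))
    for onset, dur, f in design.finger_onsets:
        i0 = int(round(onset / _DT))
        i1 = min(int(round((onset + dur) / _DT)), n_fine)
        box[FINGERS.index(f), i0:i1] = 1.0
    if include_gaps:
        for t, f in design.gap_schedule:
            i0 = int(round(t / _DT))
            i1 = min(i0 + max(int(round(0.18 / _DT)), 1), n_fine)
            box[FINGERS.index(f), i0:i1] = 0.0
    t_h = np.arange(0, 32.0, _DT)
    h = double_gamma_hrf(t_h, **hrf)
    step = int(round(design.TR / _DT))
    out = np.empty((design.n_volumes, 5))
    for k in range(5):
        conv = np.convolve(box[k], h)[:n_fine] * _DT
        out[:, k] = conv[::step][:design.n_volumes]
    return out


def prf_weights(centers: np.ndarray, widths: np.ndarray) -> np.ndarray:
    """(V, 5) Gaussian pRF weight of each finger's axis position."""
    cx = np.array([FINGER_CENTERS[f] for f in FINGERS])
    w = np.exp(-((centers[:, None] - cx[None, :]) ** 2)
               / (2.0 * widths[:, None] ** 2))
    return np.where(np.isfinite(w), w, 0.0)


def simulate_bold(topography: FingerTopography, design: StimulusDesign,
                  hrf: dict | None = None, noise_sd: float = 0.8,
                  rng: np.random.Generator | int | None = None) -> BoldTimeSeries:
    """Simulate per-vertex BOLD: Gaussian pRF drive convolved with the HRF."""
    widths = topography.prf_width
    if np.any(widths[np.isfinite(widths)] <= 0):
        raise InvalidArgumentError("pRF width sigma must be positive")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    reg = finger_regressors(design, hrf)          # (n_vol, 5)
    w = prf_weights(topography.prf_center, widths)  # (V, 5)
    sig = w @ reg.T
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd, sig.shape)
    return BoldTimeSeries(values=sig, TR=design.TR)


# ---------------------------------------------------------------------------
# Cohorts

@dataclass
class Cohort:
    participants: list[Participant]
    mesh: CorticalPatchMesh

    def __len__(self):
        return len(self.participants)

    def __iter__(self):
        return iter(self.participants)


def make_cohort(n: int, truth_template: GroundTruthSpec,
                between_subject_sd: float = 0.26, seed: int = 0,
                mesh: CorticalPatchMesh | None = None,
                amplitude_rel_sd: float | None = None) -> Cohort:
    """Generate ``n`` synthetic participants.

    ``between_subject_sd`` jitters each participant's finger band centers
    (mm, shared shift plus independent per-band wobble).  Canonical profile
    amplitude is jittered with relative sd ``amplitude_rel_sd`` (default
    scales with ``between_subject_sd``; exactly 0 when the jitter is 0, so a
    zero-jitter cohort shares identical truth and differs only in noise).
    """
    if n < 2:
        raise InvalidArgumentError("a cohort needs n >= 2 participants")
    if mesh is None:
        mesh = build_patch_mesh(40, 60, 0.26)
    if amplitude_rel_sd is None:
        amplitude_rel_sd = 0.115 * between_subject_sd
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n)
    parts = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        centers = truth_template.finger_band_centers.copy()
        if between_subject_sd > 0:
            centers = centers + rng.normal(0.0, between_subject_sd)
            centers = centers + rng.normal(0.0, between_subject_sd / 2.0, 5)
            centers.sort()
            # keep bands inside the patch, preserving strict ordering
            y_max = mesh.surface_coords[:, 1].max()
            half = truth_template.band_width / 2.0
            centers = np.clip(centers, half, y_max - half)
            for k in range(1, 5):
                centers[k] = max(centers[k], centers[k - 1] + 1e-6)
            for k in range(3, -1, -1):
                centers[k] = min(centers[k], centers[k + 1] - 1e-6)
        amp = 1.0
        if amplitude_rel_sd > 0:
            amp = 1.0 + rng.normal(0.0, amplitude_rel_sd)
        truth = replace(
            truth_template, finger_band_centers=centers, amplitude_scale=amp,
            seed=int(rng.integers(0, 2 ** 31 - 1)))
        parts.append(synthesize_participant(mesh, truth, label=f"P{i + 1:02d}"))
    return Cohort(participants=parts, mesh=mesh)
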