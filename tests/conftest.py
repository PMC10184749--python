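import numpy as np
import pytest

from somatolayers import synthdata as sd


ZERO_NOISE = {"qT1": 0.0, "nQSM": 0.0, "pQSM": 0.0, "aQSM": 0.0}


@pytest.fixture(scope="session")
def default_mesh():
    return sd.build_patch_mesh(40, 60, 0.26)


@pytest.fixture(scope="session")
def small_mesh():
    return sd.build_patch_mesh(20, 12, 0.26)


@pytest.fixture(scope="session")
def noiseless_participant(default_mesh):
    truth = sd.default_truth(default_mesh, seed=7, noise_sd=dict(ZERO_NOISE))
    return sd.synthesize_participant(default_mesh, truth)


@pytest.fixture(scope="session")
def phase_design():
    return sd.generate_design("phase_encoded", seed=11)


@pytest.fixture(scope="session")
def blocked_design():
    return sd.generate_design("blocked", seed=11)


def true_peak_vertices(participant):
    """Ground-truth activation peaks: vertex nearest each band center on the
    central column (independent of the GLM route)."""
    mesh = participant.mesh
    s = mesh.surface_coords
    x_mid = (s[:, 0].min() + s[:, 0].max()) / 2.0
    peaks = {}
    for f, cy in zip(sd.FINGERS, participant.truth.finger_band_centers):
        d = (s[:, 0] - x_mid) ** 2 + (s[:, 1] - cy) ** 2
        peaks[f] = int(np.argmin(d))
    return peaks
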