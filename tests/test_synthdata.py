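"""Generator tests: meshes, canonical profiles, injections, designs, BOLD."""

import numpy as np
import pytest

from somatolayers import geodesy, synthdata as sd
from somatolayers.core import FINGERS, InvalidArgumentError

from conftest import ZERO_NOISE


class TestPatchMesh:
    def test_smallest_grid(self):
        m = sd.build_patch_mesh(2, 2, 1.0)
        assert m.n_vertices == 4
        assert len(m.triangles) == 2
        assert set(np.round(m.edge_lengths, 6)) <= {1.0, round(np.sqrt(2), 6)}

    def test_default_patch_spacing(self):
        m = sd.build_patch_mesh(40, 60, 0.26)
        assert m.n_vertices == 2400
        assert 0.26 <= m.edge_lengths.mean() <= 0.37
        # nominal spacing matches the grid edges (non-diagonal) within 1%
        grid_edges = m.edge_lengths[m.edge_lengths < 0.3]
        assert abs(grid_edges.mean() - 0.26) < 0.01 * 0.26

    def test_bent_sheet_geodesic_exceeds_chord(self):
        m = sd.build_patch_mesh(3, 3, 1.0, curvature=2.0)
        path = geodesy.shortest_path(m, 0, 8)
        chord = np.linalg.norm(m.vertex_coords[8] - m.vertex_coords[0])
        assert path.length > chord + 1e-6

    def test_connected_and_valid(self):
        m = sd.build_patch_mesh(5, 4, 0.3)
        m.validate()
        # single component: BFS from 0 reaches everything
        seen = {0}
        frontier = [0]
        adj = {}
        for a, b in m.edges:
            adj.setdefault(int(a), []).append(int(b))
            adj.setdefault(int(b), []).append(int(a))
        while frontier:
            u = frontier.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    frontier.append(v)
        assert len(seen) == m.n_vertices

    @pytest.mark.parametrize("rows,cols,spacing", [(1, 5, 0.3), (5, 1, 0.3),
                                                   (5, 5, 0.0)])
    def test_invalid_dimensions(self, rows, cols, spacing):
        with pytest.raises(InvalidArgumentError):
            sd.build_patch_mesh(rows, cols, spacing)


class TestCanonicalProfiles:
    def test_qt1_compartment_means(self):
        prof = sd.canonical_depth_profile("qT1")
        outer, middle, inner = prof[:4].mean(), prof[4:11].mean(), prof[11:19].mean()
        assert abs(outer / 2105.19 - 1) < 0.05
        assert abs(middle / 1883.79 - 1) < 0.05
        assert abs(inner / 1658.25 - 1) < 0.05

    def test_qt1_envelope_decreasing(self):
        prof = sd.canonical_depth_profile("qT1")
        assert prof[20] < prof[0]

    def test_nqsm_shape(self):
        prof = sd.canonical_depth_profile("nQSM")
        assert np.all(prof <= 0)
        assert 4 <= np.argmax(prof) <= 10  # middle-compartment depth (0-based)

    def test_pqsm_two_peaks(self):
        from scipy.signal import argrelmax
        prof = sd.canonical_depth_profile("pQSM")
        assert np.all(prof >= 0)
        peaks = argrelmax(prof)[0]
        assert any(4 <= p <= 10 for p in peaks)    # upper peak in middle
        assert any(11 <= p <= 18 for p in peaks)   # lower peak in inner

    def test_aqsm_decreasing(self):
        prof = sd.canonical_depth_profile("aQSM")
        assert np.all(np.diff(prof) <= 0)

    def test_unknown_contrast(self):
        with pytest.raises(InvalidArgumentError):
            sd.canonical_depth_profile("T2star")


class TestSynthesizeParticipant:
    def test_noop_injection_reproduces_canonical(self, default_mesh):
        truth = sd.default_truth(default_mesh, seed=0, noise_sd=dict(ZERO_NOISE))
        p = sd.synthesize_participant(default_mesh, truth)
        canon = sd.canonical_depth_profile("qT1")
        assert np.allclose(p.maps["qT1"], canon[None, :])

    def test_septum_elevates_border_middle_depths(self, default_mesh):
        truth = sd.default_truth(default_mesh, seed=0, noise_sd=dict(ZERO_NOISE),
                                 septa=[sd.Septum("D1-D2", 80.0, 0.5)])
        p = sd.synthesize_participant(default_mesh, truth)
        y = default_mesh.surface_coords[:, 1]
        c = truth.finger_band_centers
        border_y = (c[0] + c[1]) / 2
        border_v = np.argmin(np.abs(y - border_y) + default_mesh.surface_coords[:, 0])
        peak_v = np.argmin(np.abs(y - c[0]) + default_mesh.surface_coords[:, 0])
        mid = slice(4, 11)
        elev = p.maps["qT1"][border_v, mid].mean() - p.maps["qT1"][peak_v, mid].mean()
        assert elev >= 40.0

    def test_gradient_recovered_by_ols(self, default_mesh):
        truth = sd.default_truth(default_mesh, seed=0, noise_sd=dict(ZERO_NOISE),
                                 gradient_slope_qt1=100.0)
        p = sd.synthesize_participant(default_mesh, truth)
        d = sd.normalized_span_position(truth, default_mesh.surface_coords[:, 1])
        vals = p.maps["qT1"][:, 7]
        slope = np.polyfit(d, vals, 1)[0]
        assert abs(slope - 100.0) <= 1.0

    def test_injection_linearity(self, default_mesh):
        base = dict(seed=0, noise_sd=dict(ZERO_NOISE))
        sa = [sd.Septum("D1-D2", 60.0, 0.5)]
        sb = [sd.Septum("D3-D4", 40.0, 0.7)]
        ta = sd.default_truth(default_mesh, septa=sa, **base)
        tb = sd.default_truth(default_mesh, septa=sb, **base)
        tab = sd.default_truth(default_mesh, septa=sa + sb, **base)
        # the injected fields add exactly
        fa = sd.septum_field(default_mesh, ta)
        fb = sd.septum_field(default_mesh, tb)
        fab = sd.septum_field(default_mesh, tab)
        assert np.array_equal(fa + fb, fab)
        # and the generated maps follow to numerical precision
        pa = sd.synthesize_participant(default_mesh, ta)
        pb = sd.synthesize_participant(default_mesh, tb)
        pab = sd.synthesize_participant(default_mesh, tab)
        p0 = sd.synthesize_participant(
            default_mesh, sd.default_truth(default_mesh, **base))
        lhs = (pa.maps["qT1"] - p0.maps["qT1"]) + (pb.maps["qT1"] - p0.maps["qT1"])
        rhs = pab.maps["qT1"] - p0.maps["qT1"]
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_noiseless_gradient_exactly_linear_every_depth(self, default_mesh):
        truth = sd.default_truth(default_mesh, seed=0, noise_sd=dict(ZERO_NOISE),
                                 gradient_slope_qt1=80.0)
        p = sd.synthesize_participant(default_mesh, truth)
        y = default_mesh.surface_coords[:, 1]
        d = sd.normalized_span_position(truth, y)
        for depth in (0, 7, 15, 20):
            vals = p.maps["qT1"][:, depth]
            fitted = np.polyval(np.polyfit(d, vals, 1), d)
            assert np.allclose(vals, fitted, atol=1e-8)

    def test_seed_determinism(self, default_mesh):
        truth = sd.default_truth(default_mesh, seed=42)
        p1 = sd.synthesize_participant(default_mesh, truth)
        p2 = sd.synthesize_participant(default_mesh, truth)
        for c in p1.maps:
            assert np.array_equal(p1.maps[c], p2.maps[c])

    def test_bands_outside_patch_rejected(self, small_mesh):
        with pytest.raises(InvalidArgumentError):
            truth = sd.default_truth(small_mesh, seed=0)
            truth.finger_band_centers = truth.finger_band_centers + 100.0
            sd.synthesize_participant(small_mesh, truth)


class TestStimulusDesigns:
    def test_phase_encoded_constants(self, phase_design):
        assert phase_design.n_volumes == 256
        assert phase_design.duration == 512.0
        assert phase_design.cycle_duration == 25.6

    def test_gap_counts(self):
        for seed in (0, 1, 2):
            des = sd.generate_design("phase_encoded", seed=seed)
            gaps_per_finger = {f: 0 for f in FINGERS}
            for _, f in des.gap_schedule:
                gaps_per_finger[f] += 1
            assert all(v == 3 for v in gaps_per_finger.values())
            assert len(des.gap_schedule) == 15

    def test_reverse_equals_forward_reversed_within_cycle(self):
        fwd = sd.generate_design("phase_encoded", seed=3, direction="forward")
        rev = sd.generate_design("phase_encoded", seed=3, direction="reverse")
        for ci in range(fwd.n_cycles):
            f_cycle = [f for _, _, f in fwd.finger_onsets[5 * ci:5 * ci + 5]]
            r_cycle = [f for _, _, f in rev.finger_onsets[5 * ci:5 * ci + 5]]
            assert r_cycle == f_cycle[::-1]

    def test_indivisible_timing_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sd.generate_design("phase_encoded", per_finger_duration=5.0,
                               n_cycles=3, TR=2.0)

    def test_blocked_constraints(self, blocked_design):
        seq = [f for _, _, f in blocked_design.finger_onsets]
        counts = {f: seq.count(f) for f in FINGERS}
        assert all(v == 10 for v in counts.values())
        for i in range(2, len(seq)):
            assert not (seq[i] == seq[i - 1] == seq[i - 2])
        # pauses: 2 s (70%) and 6 s (30%) between consecutive stimulations
        pauses = [round(blocked_design.finger_onsets[i + 1][0]
                        - blocked_design.finger_onsets[i][0]
                        - blocked_design.finger_onsets[i][1], 6)
                  for i in range(len(seq) - 1)]
        assert set(pauses) <= {2.0, 6.0}


class TestSimulateBold:
    def test_phase_delay_between_fingers(self, default_mesh, phase_design):
        truth = sd.default_truth(default_mesh, seed=0, noise_sd=dict(ZERO_NOISE))
        p = sd.synthesize_participant(default_mesh, truth)
        bold = sd.simulate_bold(p.topography, phase_design, noise_sd=0.0)
        cycle = phase_design.cycle_duration
        # volumes do not align with cycles (25.6 s vs TR 2 s): bin by phase
        times = np.arange(phase_design.n_volumes) * phase_design.TR
        phases = np.round(times % cycle, 6)
        order = np.argsort(phases)
        peaks = {}
        for f in ("D1", "D3"):
            roi = p.topography.roi(f)
            v = roi[len(roi) // 2]
            # skip the first cycle (HRF ramp-in)
            keep = times >= cycle
            ph, vals = phases[keep], bold.values[v][keep]
            uniq = np.unique(ph)
            avg = np.array([vals[ph == u].mean() for u in uniq])
            peaks[f] = uniq[np.argmax(avg)]
        delay = (peaks["D3"] - peaks["D1"]) % cycle
        assert abs(delay - 2 * 5.12) <= 2.0

    def test_flat_prf_limit(self, default_mesh, phase_design):
        import dataclasses
        truth = sd.default_truth(default_mesh, seed=0, noise_sd=dict(ZERO_NOISE))
        p = sd.synthesize_participant(default_mesh, truth)
        topo_wide = dataclasses.replace(
            p.topography, prf_width=np.full(default_mesh.n_vertices, 25.0))
        narrow = sd.simulate_bold(p.topography, phase_design, noise_sd=0.0)
        wide = sd.simulate_bold(topo_wide, phase_design, noise_sd=0.0)
        v = p.topography.roi("D3")[10]

        def cv(x):
            return x.std() / x.mean()

        assert cv(wide.values[v]) < cv(narrow.values[v])

    def test_volume_count_and_finiteness(self, default_mesh, phase_design):
        truth = sd.default_truth(default_mesh, seed=1)
        p = sd.synthesize_participant(default_mesh, truth)
        bold = sd.simulate_bold(p.topography, phase_design, noise_sd=0.5, rng=4)
        assert bold.n_volumes == phase_design.n_volumes
        assert np.all(np.isfinite(bold.values))

    def test_invalid_sigma(self, default_mesh, phase_design):
        truth = sd.default_truth(default_mesh, seed=0)
        p = sd.synthesize_participant(default_mesh, truth)
        p.topography.prf_width[p.topography.roi("D1")[0]] = -1.0
        with pytest.raises(InvalidArgumentError):
            sd.simulate_bold(p.topography, phase_design)


class TestMakeCohort:
    def test_zero_jitter_identical_truth(self, small_mesh):
        truth = sd.default_truth(small_mesh, seed=0)
        cohort = sd.make_cohort(4, truth, between_subject_sd=0.0, seed=1,
                                mesh=small_mesh)
        c0 = cohort.participants[0].truth
        for p in cohort.participants[1:]:
            assert np.array_equal(p.truth.finger_band_centers,
                                  c0.finger_band_centers)
            assert p.truth.amplitude_scale == c0.amplitude_scale == 1.0
        # still different noise realizations
        assert not np.array_equal(cohort.participants[0].maps["qT1"],
                                  cohort.participants[1].maps["qT1"])

    def test_seed_determinism(self, small_mesh):
        truth = sd.default_truth(small_mesh, seed=0)
        a = sd.make_cohort(5, truth, between_subject_sd=0.2, seed=1,
                           mesh=small_mesh)
        b = sd.make_cohort(5, truth, between_subject_sd=0.2, seed=1,
                           mesh=small_mesh)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.maps["qT1"], pb.maps["qT1"])
            assert np.array_equal(pa.truth.finger_band_centers,
                                  pb.truth.finger_band_centers)

    def test_too_small_cohort(self, small_mesh):
        truth = sd.default_truth(small_mesh, seed=0)
        with pytest.raises(InvalidArgumentError):
            sd.make_cohort(1, truth, mesh=small_mesh)
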