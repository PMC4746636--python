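"""Compaction observables on constructed geometries and their invariances."""

import numpy as np
import pytest

from telocompact.builder import build_protein, sample_wlc_positions
from telocompact.forcefield import BeadKind, DNAChain, SystemState
from telocompact.observables import (
    CompactionReport,
    LoopReport,
    StageLabel,
    StageThresholds,
    analyze_frame,
    classify_stage,
    detect_dimers,
    dna_contacts,
    globule_and_loop,
    occupancy,
    persistence_length,
    sliding_msd,
    zipped_length,
)
from telocompact.synth import gen_fixture_trajectory


def _chain(pos):
    return SystemState(DNAChain(pos, np.full(len(pos), BeadKind.DNA_SPECIFIC_HIGH, dtype=np.int8)), [], 0.0)


class TestOccupancy:
    def test_no_proteins_zero(self):
        pos = np.zeros((20, 3))
        pos[:, 0] = np.arange(20)
        assert occupancy(_chain(pos)) == 0.0

    def test_full_decoration(self):
        pos = np.zeros((10, 3))
        pos[:, 0] = np.arange(10)
        # Myb faces +x by default; the site then sits 1.0 nm from each bead
        prots = [build_protein(p - np.array([1.5, 0.0, 0.0])) for p in pos]
        state = SystemState(_chain(pos).dna, prots, 0.0)
        assert occupancy(state) == 1.0


class TestDimers:
    def test_isolated_proteins_no_edges(self):
        prots = [build_protein(np.array([20.0 * k, 0, 0])) for k in range(4)]
        pos = np.zeros((12, 3))
        pos[:, 1] = 50 + np.arange(12)
        n, edges, deg = detect_dimers(SystemState(_chain(pos).dna, prots, 0.0))
        assert n == 0 and len(edges) == 0

    def test_constructed_pair_one_edge(self):
        # dimer sites on +z faces: stack two proteins dimer-face to dimer-face
        s2 = np.sqrt(0.5)
        q_up = np.array([s2, 0.0, -s2, 0.0])  # Myb -> +z, anti-Myb dimer -> -z
        q_down = np.array([s2, 0.0, s2, 0.0])
        prots = [
            build_protein(np.array([0.0, 0, 0.7]), q_up),
            build_protein(np.array([0.0, 0, -0.7]), q_down),
        ]
        pos = np.zeros((12, 3))
        pos[:, 1] = 50 + np.arange(12)
        n, edges, deg = detect_dimers(SystemState(_chain(pos).dna, prots, 0.0))
        assert n == 1 and deg.max() == 1

    def test_degree_bounded_by_dimer_valence(self):
        frame = gen_fixture_trajectory("globule_with_loop").frames[0]
        _, _, deg = detect_dimers(frame)
        assert deg.max() <= 3


class TestContactsAndZipping:
    def test_straight_chain_empty(self):
        pos = np.zeros((100, 3))
        pos[:, 0] = np.arange(100)
        assert len(dna_contacts(_chain(pos))) == 0

    def test_hairpin_contacts_on_antidiagonal(self):
        frame = gen_fixture_trajectory("hairpin").frames[0]
        contacts = dna_contacts(frame)
        assert len(contacts) > 0
        apex = 50
        assert np.all(np.abs(contacts.sum(axis=1) - 2 * apex) <= 6)

    def test_min_separation_guard(self):
        pos = np.zeros((30, 3))
        with pytest.raises(ValueError):
            dna_contacts(_chain(pos), min_separation=5)

    def test_zipped_empty(self):
        assert zipped_length(np.zeros((0, 2), dtype=int)) == 0.0

    def test_perfect_hairpin_run(self):
        # antiparallel ladder: contacts (i, 69 - i) for i = 0..29
        contacts = np.array([(i, 69 - i) for i in range(30)])
        assert zipped_length(contacts) == 30.0

    def test_parallel_register_counts(self):
        contacts = np.array([(i, i + 40) for i in range(25)])
        assert zipped_length(contacts) == 25.0

    def test_shuffled_contacts_short_runs(self):
        rng = np.random.default_rng(0)
        lengths = []
        for _ in range(20):
            i = rng.integers(0, 150, size=40)
            j = i + rng.integers(15, 120, size=40)
            lengths.append(zipped_length(np.stack([i, j], axis=1)))
        assert np.median(lengths) <= 2.0


class TestGlobuleAndLoop:
    def test_extended_chain_no_compaction(self):
        frame = gen_fixture_trajectory("free_dna").frames[0]
        beads, compacted, loop = globule_and_loop(frame)
        assert compacted == 0.0 and not loop.present

    def test_constructed_loop_length(self):
        frame = gen_fixture_trajectory("globule_with_loop").frames[0]
        beads, compacted, loop = globule_and_loop(frame)
        assert loop.present
        assert loop.length_nm == 60.0
        assert (loop.start, loop.end) == (500, 559)
        assert compacted > 300.0

    def test_loop_requires_protein_freeness(self):
        frame = gen_fixture_trajectory("globule_with_loop").frames[0].copy()
        # park a protein on the loop: it is no longer protein-free
        loop_bead = frame.dna.positions[530]
        frame.proteins.append(build_protein(loop_bead + np.array([0.0, 0.0, 1.3])))
        _, _, loop = globule_and_loop(frame)
        assert not (loop.present and loop.start <= 530 <= loop.end)


class TestStageClassifier:
    def test_zero_report_free(self):
        rep = CompactionReport(0.0, 0, 0, 0.0, 50.0, 0.0, LoopReport(False))
        assert classify_stage(rep) == StageLabel.FREE

    def test_decision_list_order(self):
        th = StageThresholds()
        rep = CompactionReport(0.4, 3, 50, th.threshold_z + 1, 30.0, th.threshold_g + 1,
                               LoopReport(False), captured_crossover=True, multistrand=True)
        assert classify_stage(rep, th) == StageLabel.GLOBULE
        rep.compacted_length = 0.0
        assert classify_stage(rep, th) == StageLabel.MULTISTRAND
        rep.multistrand = False
        assert classify_stage(rep, th) == StageLabel.ZIPPED
        rep.zipped_length = 0.0
        assert classify_stage(rep, th) == StageLabel.CROSSOVER_CAPTURED
        rep.captured_crossover = False
        assert classify_stage(rep, th) == StageLabel.DIMERS_ON_DNA
        rep.n_dimers = 0
        assert classify_stage(rep, th) == StageLabel.MONOMERS_BOUND
        rep.occupancy = 0.0
        assert classify_stage(rep, th) == StageLabel.FREE

    def test_fixture_stages(self):
        assert analyze_frame(gen_fixture_trajectory("free_dna").frames[0]).stage == StageLabel.FREE
        assert (
            analyze_frame(gen_fixture_trajectory("hairpin").frames[0]).stage
            == StageLabel.CROSSOVER_CAPTURED
        )
        assert analyze_frame(gen_fixture_trajectory("zipped").frames[0]).stage == StageLabel.ZIPPED
        assert (
            analyze_frame(gen_fixture_trajectory("globule_with_loop").frames[0]).stage
            == StageLabel.GLOBULE
        )


class TestFrameInvariances:
    def test_rigid_motion_invariance(self):
        frame = gen_fixture_trajectory("globule_with_loop").frames[0]
        base = analyze_frame(frame)
        moved = frame.copy()
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_rotvec([0.3, -0.2, 0.9])
        shift = np.array([13.0, -7.0, 5.0])
        moved.dna.positions[:] = rot.apply(moved.dna.positions) + shift
        for p in moved.proteins:
            p.center[:] = rot.apply(p.center) + shift
            q = rot * Rotation.from_quat(np.roll(p.orientation, -1))
            p.orientation[:] = np.roll(q.as_quat(), 1)
        out = analyze_frame(moved)
        assert out.occupancy == base.occupancy
        assert out.compacted_length == pytest.approx(base.compacted_length)
        assert out.zipped_length == base.zipped_length
        assert out.loop.length_nm == base.loop.length_nm

    def test_repeat_evaluation_identical(self):
        frame = gen_fixture_trajectory("zipped").frames[0]
        a, b = analyze_frame(frame), analyze_frame(frame)
        assert (a.occupancy, a.n_contacts, a.zipped_length, a.compacted_length) == (
            b.occupancy, b.n_contacts, b.zipped_length, b.compacted_length
        )


class TestSlidingMSD:
    def _traj_from_indices(self, indices):
        from telocompact.dynamics import Trajectory

        frames = []
        pos = np.zeros((200, 3))
        pos[:, 0] = np.arange(200)
        for idx in indices:
            prot = build_protein(pos[idx] + np.array([1.5, 0.0, 0.0]))
            frames.append(SystemState(DNAChain(pos.copy(), np.ones(200, dtype=np.int8)), [prot], 0.0))
        return Trajectory(frames, list(map(float, range(len(indices)))), 1)

    def test_static_protein_zero_slope(self):
        traj = self._traj_from_indices([100] * 30)
        slope, _, _ = sliding_msd(traj, 0)
        assert slope == pytest.approx(0.0, abs=1e-9)

    def test_random_walk_slope(self):
        rng = np.random.default_rng(0)
        steps = rng.choice([-2, -1, 0, 1, 2], size=400)
        idx = np.clip(100 + np.cumsum(steps), 5, 195)
        traj = self._traj_from_indices(list(idx))
        slope, _, _ = sliding_msd(traj, 0)
        assert slope == pytest.approx(np.var(steps), rel=0.35)

    def test_detached_protein_rejected(self):
        from telocompact.dynamics import Trajectory

        pos = np.zeros((50, 3))
        pos[:, 0] = np.arange(50)
        frames = [
            SystemState(DNAChain(pos.copy(), np.ones(50, dtype=np.int8)),
                        [build_protein(np.array([0.0, 50.0, 0.0]))], 0.0)
            for _ in range(10)
        ]
        with pytest.raises(ValueError):
            sliding_msd(Trajectory(frames, list(map(float, range(10))), 1), 0)


class TestPersistenceEstimator:
    def test_static_wlc_recovers_target(self):
        rng = np.random.default_rng(3)
        k = 45.93224120562637
        frames = [sample_wlc_positions(200, k, rng) for _ in range(400)]
        fit = persistence_length(frames)
        assert fit.lp_nm == pytest.approx(46.1, rel=0.06)

    def test_floppy_chain_matches_quadrature(self):
        from telocompact.builder import bend_mean_cos

        rng = np.random.default_rng(4)
        frames = [sample_wlc_positions(200, 2.0, rng) for _ in range(200)]
        fit = persistence_length(frames, s_min=1, s_max=4, min_r_squared=0.0)
        expected = -1.0 / np.log(bend_mean_cos(2.0))
        assert fit.lp_nm == pytest.approx(expected, rel=0.1)
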