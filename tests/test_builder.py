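"""System construction and calibration of underdetermined constants."""

import numpy as np
import pytest

from telocompact.builder import (
    build_dna,
    calibrate_bending,
    calibrate_epsilons,
    concentration_uM,
    bend_mean_cos,
    init_system,
    sample_wlc_positions,
)
from telocompact.forcefield import BeadKind, ForceField


class TestBuildDNA:
    def test_default_telomere_layout(self):
        dna = build_dna()
        assert dna.n_beads == 1400
        assert np.all(dna.kinds[200:1200] == BeadKind.DNA_SPECIFIC_HIGH)
        assert np.all(dna.kinds[:200] == BeadKind.DNA_SPECIFIC_LOW)
        assert np.all(dna.kinds[1200:] == BeadKind.DNA_SPECIFIC_LOW)

    def test_all_core_when_no_flank(self):
        dna = build_dna(10, 0, 10)
        assert np.all(dna.kinds == BeadKind.DNA_SPECIFIC_HIGH)

    def test_inconsistent_layout_rejected(self):
        with pytest.raises(ValueError):
            build_dna(1400, 300, 1000)


class TestInitSystem:
    def test_reference_system(self):
        state = init_system(n_proteins=40, box_side=500.0, seed=1)
        assert len(state.proteins) == 40
        assert state.dna.n_beads == 1400
        # circle diameter ~446 nm fits the box
        ext = state.dna.positions.max(axis=0) - state.dna.positions.min(axis=0)
        assert ext.max() < 500.0
        # no core overlaps among protein centers / DNA
        from scipy.spatial import cKDTree

        centers = np.array([p.center for p in state.proteins])
        d, _ = cKDTree(state.dna.positions).query(centers)
        assert d.min() > 2.0
        dd = cKDTree(centers).query_pairs(2.0)
        assert len(dd) == 0

    def test_reproducible_under_seed(self):
        a = init_system(n_proteins=10, box_side=500.0, seed=7)
        b = init_system(n_proteins=10, box_side=500.0, seed=7)
        assert np.array_equal(a.dna.positions, b.dna.positions)
        for pa, pb in zip(a.proteins, b.proteins):
            assert np.array_equal(pa.center, pb.center)
            assert np.array_equal(pa.orientation, pb.orientation)

    def test_dna_only(self):
        state = init_system(n_proteins=0, box_side=500.0, seed=0)
        assert state.proteins == []

    def test_circle_must_fit_box(self):
        with pytest.raises(ValueError):
            init_system(n_proteins=0, box_side=400.0, seed=0)


class TestConcentration:
    def test_reference_value(self):
        c = concentration_uM(200, 500.0)
        assert f"{c:.2g}" == "2.7"

    def test_zero(self):
        assert concentration_uM(0, 500.0) == 0.0

    def test_linearity(self):
        assert concentration_uM(400, 500.0) == pytest.approx(2 * concentration_uM(200, 500.0))


class TestCalibrateBending:
    def test_self_consistency(self):
        k = calibrate_bending(46.1)
        assert bend_mean_cos(k) == pytest.approx(np.exp(-1.0 / 46.1), abs=1e-10)

    def test_monotone_in_target(self):
        assert calibrate_bending(500.0) > calibrate_bending(46.1)

    def test_target_below_bond_rejected(self):
        with pytest.raises(ValueError):
            calibrate_bending(0.5)


class TestWLCSampler:
    def test_bond_lengths_exact(self):
        rng = np.random.default_rng(0)
        pos = sample_wlc_positions(50, 46.0, rng)
        b = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        assert np.allclose(b, 1.0, atol=1e-9)

    def test_mean_cos_matches_quadrature(self):
        rng = np.random.default_rng(1)
        cos = []
        for _ in range(60):
            pos = sample_wlc_positions(100, 20.0, rng)
            t = np.diff(pos, axis=0)
            t /= np.linalg.norm(t, axis=1, keepdims=True)
            cos.append(np.mean(np.sum(t[:-1] * t[1:], axis=1)))
        assert np.mean(cos) == pytest.approx(bend_mean_cos(20.0), abs=0.01)


class TestCalibrateEpsilons:
    """Logic of the sensitivity verification, driven by a stub protocol."""

    def _stub(self, table):
        def protocol(ff, seed):
            spec = ff.epsilon_lj[BeadKind.MYB_SITE, BeadKind.DNA_SPECIFIC_HIGH]
            dim = ff.epsilon_lj[BeadKind.DIMER_SITE, BeadKind.DIMER_SITE]
            basic = ff.charge_by_kind[BeadKind.BASIC_SITE]
            key = (round(spec, 3), round(dim, 3), round(basic, 3))
            return table[key], 12.0

        return protocol

    def test_accepts_sensitive_table(self):
        ff = ForceField()
        full = (5.0, 6.0, 2.1)
        table = {full: 20.0, (2.5, 6.0, 2.1): 0.0, (5.0, 3.0, 2.1): 0.0, (5.0, 6.0, 1.05): 0.0}
        out, records = calibrate_epsilons(ff, self._stub(table))
        assert out is ff
        assert records[0].condition == "full"
        assert all(not any(rec.compacted) for rec in records[1:])

    def test_rejects_insensitive_table(self):
        ff = ForceField()
        table = {(5.0, 6.0, 2.1): 20.0, (2.5, 6.0, 2.1): 20.0, (5.0, 3.0, 2.1): 0.0, (5.0, 6.0, 1.05): 0.0}
        with pytest.raises(RuntimeError):
            calibrate_epsilons(ff, self._stub(table))
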