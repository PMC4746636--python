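"""Energy/force terms: closed-form values, numerical-gradient oracles, and
pair-symmetry / sign properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from telocompact.builder import bend_mean_cos
from telocompact.electrostatics import (
    bjerrum_length_nm,
    coulomb_scale_kBT_nm,
    manning_effective_charge_density,
    osf_persistence_length_nm,
)
from telocompact.forcefield import (
    BeadKind,
    DNAChain,
    ForceField,
    SystemState,
    bend_energy,
    bond_energy,
    shifted_lj,
    total_energy,
    yukawa,
    yukawa_force,
)


class TestShiftedLJ:
    def test_force_vanishes_at_minimum(self):
        r = 1.0 + 2.0 ** (1.0 / 6.0)
        _, force = shifted_lj(r, eps=2.0, sigma=1.0, delta=1.0, r_cut=2.0)
        assert force == pytest.approx(0.0, abs=1e-10)

    def test_zero_beyond_truncation(self):
        assert shifted_lj(2.0 + 1.0 + 0.5, eps=1.0, sigma=1.0, delta=1.0, r_cut=2.0) == (0.0, 0.0)

    def test_energy_continuous_at_cutoff(self):
        e_in, _ = shifted_lj(2.999999, eps=3.0, sigma=1.0, delta=1.0, r_cut=2.0)
        assert e_in == pytest.approx(0.0, abs=1e-4)

    def test_force_matches_numerical_gradient(self):
        # eps=1, sigma=1, delta=0, r=1.3 (the stated oracle configuration)
        h = 1e-6
        e_plus, _ = shifted_lj(1.3 + h, 1.0, 1.0, 0.0, 2.0)
        e_minus, _ = shifted_lj(1.3 - h, 1.0, 1.0, 0.0, 2.0)
        numeric = -(e_plus - e_minus) / (2 * h)
        _, force = shifted_lj(1.3, 1.0, 1.0, 0.0, 2.0)
        assert force == pytest.approx(numeric, rel=1e-6)

    def test_core_overlap_rejected(self):
        with pytest.raises(ValueError):
            shifted_lj(0.9, 1.0, 1.0, delta=1.0, r_cut=2.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        r=st.floats(0.9, 2.4),
        eps=st.floats(0.05, 10.0),
        delta=st.floats(0.0, 0.5),
    )
    def test_gradient_property(self, r, eps, delta):
        if r - delta < 0.7:
            return
        h = 1e-6
        e_p, _ = shifted_lj(r + h, eps, 1.0, delta, 2.0)
        e_m, _ = shifted_lj(r - h, eps, 1.0, delta, 2.0)
        if e_p == 0.0 or e_m == 0.0:
            return  # straddles the truncation edge
        _, force = shifted_lj(r, eps, 1.0, delta, 2.0)
        assert force == pytest.approx(-(e_p - e_m) / (2 * h), rel=1e-4, abs=1e-8)


class TestYukawa:
    def test_zero_charge(self):
        for r in (0.5, 2.0, 9.0):
            assert yukawa(r, 0.0, -1.4) == 0.0

    def test_coulomb_scale_from_constants(self):
        # e^2/(4 pi 80 eps0 kBT) at 298 K ~ 0.70 kBT nm
        assert coulomb_scale_kBT_nm() == pytest.approx(0.70, abs=0.01)
        # DNA-DNA bead pair prefactor 1.96 e^2 * scale ~ 1.37 kBT nm
        assert 1.4 * 1.4 * coulomb_scale_kBT_nm() == pytest.approx(1.37, abs=0.02)

    def test_force_matches_numerical_gradient_at_2nm(self):
        h = 1e-6
        numeric = -(yukawa(2 + h, -1.4, 2.1) - yukawa(2 - h, -1.4, 2.1)) / (2 * h)
        assert yukawa_force(2.0, -1.4, 2.1) == pytest.approx(numeric, rel=1e-6)

    def test_signs(self):
        assert yukawa(2.0, -1.4, -1.4) > 0  # DNA-DNA repulsive
        assert yukawa(2.0, -1.4, +2.1) < 0  # DNA-basic attractive

    def test_coincident_charges_rejected(self):
        with pytest.raises(ValueError):
            yukawa(0.0, 1.0, 1.0)


class TestBondAndBend:
    def test_bond_rest_and_value(self):
        assert bond_energy(1.0, 1.0, 330.0) == 0.0
        assert bond_energy(1.1, 1.0, 330.0) == pytest.approx(1.65)
        assert bond_energy(1.05, 1.0, 330.0) == pytest.approx(bond_energy(0.95, 1.0, 330.0))

    def test_bend_straight_zero(self):
        assert bend_energy(0.0, 46.0) == 0.0

    def test_quadrature_reproduces_persistence_target(self):
        # calibrated default k_bend: -b / ln<cos theta> = 46.1 nm
        ff = ForceField()
        mc = bend_mean_cos(ff.k_bend)
        assert -1.0 / np.log(mc) == pytest.approx(46.1, rel=1e-3)

    def test_freely_jointed_limit(self):
        assert bend_mean_cos(0.0) == pytest.approx(0.0, abs=1e-12)


class TestElectrostaticsScales:
    def test_manning_effective_density(self):
        assert f"{manning_effective_charge_density():.2g}" == "1.4"

    def test_bjerrum_length(self):
        assert bjerrum_length_nm() == pytest.approx(0.70, abs=0.01)

    def test_osf_estimate(self):
        assert osf_persistence_length_nm(1.4, 1.0 / 3.0) == pytest.approx(3.09, abs=0.05)


class TestTotalEnergy:
    def _random_state(self, n=50, seed=0, charged=True):
        rng = np.random.default_rng(seed)
        pos = np.cumsum(rng.normal(0, 0.4, (n, 3)), axis=0)
        pos[:, 0] += np.arange(n)  # roughly chain-like, no overlaps
        kinds = np.full(n, BeadKind.DNA_SPECIFIC_HIGH, dtype=np.int8)
        chain = DNAChain(pos, kinds)
        return SystemState(chain, [], 0.0)

    def test_isolated_neutral_beads_zero(self):
        pos = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        chain = DNAChain(pos, np.full(2, BeadKind.DNA_SPECIFIC_HIGH, dtype=np.int8), bond_r0=50.0)
        ff = ForceField(bond_r0=50.0).without_electrostatics()
        assert total_energy(SystemState(chain, [], 0.0), ff) == pytest.approx(0.0, abs=1e-12)

    def test_straight_relaxed_chain_zero_bond_bend(self):
        pos = np.zeros((10, 3))
        pos[:, 0] = np.arange(10)
        chain = DNAChain(pos, np.full(10, BeadKind.DNA_SPECIFIC_HIGH, dtype=np.int8))
        ff = ForceField(epsilon_lj=np.zeros((6, 6))).without_electrostatics()
        assert total_energy(SystemState(chain, [], 0.0), ff) == pytest.approx(0.0, abs=1e-12)

    def test_neighbor_list_energy_matches_all_pairs(self):
        from telocompact.dynamics import IntegratorConfig, Simulation

        state = self._random_state()
        ff = ForceField()
        sim = Simulation(state, ff, IntegratorConfig(seed=0))
        kernel_energy = sim.compute_forces()
        brute = total_energy(state, ff)
        assert kernel_energy == pytest.approx(brute, abs=1e-9)

    def test_kernel_forces_match_numerical_gradient(self):
        from telocompact.dynamics import IntegratorConfig, Simulation

        state = self._random_state(n=12, seed=3)
        ff = ForceField()
        sim = Simulation(state, ff, IntegratorConfig(seed=0))
        sim.compute_forces()
        forces = sim.forces[:12].copy()
        h = 1e-6
        for i in range(12):
            for d in range(3):
                for sgn, store in ((+1, "p"), (-1, "m")):
                    pos = state.dna.positions.copy()
                    pos[i, d] += sgn * h
                    chain = DNAChain(pos, state.dna.kinds)
                    e = total_energy(SystemState(chain, [], 0.0), ff)
                    if sgn > 0:
                        ep = e
                    else:
                        em = e
                numeric = -(ep - em) / (2 * h)
                assert forces[i, d] == pytest.approx(numeric, rel=1e-5, abs=1e-7)

    def test_epsilon_table_symmetric(self):
        ff = ForceField()
        assert np.allclose(ff.epsilon_lj, ff.epsilon_lj.T)
        with pytest.raises(ValueError):
            bad = ff.epsilon_lj.copy()
            bad[0, 1] += 1.0
            ForceField(epsilon_lj=bad)


class TestProteinBody:
    def test_quaternion_normalization_enforced(self):
        from telocompact.builder import build_protein

        with pytest.raises(ValueError):
            build_protein(np.zeros(3), orientation=np.array([1.0, 0.0, 0.0, 0.01]))

    def test_site_layout(self):
        from telocompact.builder import build_protein

        p = build_protein(np.zeros(3))
        kinds = list(p.site_kinds)
        assert kinds.count(BeadKind.MYB_SITE) == 1
        assert kinds.count(BeadKind.DIMER_SITE) == 3
        assert kinds.count(BeadKind.BASIC_SITE) == 2
        # rigid-body sites sit on the cube faces
        assert np.allclose(np.linalg.norm(p.site_offsets, axis=1), 0.5)
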