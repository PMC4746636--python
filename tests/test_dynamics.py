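"""Brownian-dynamics integrator: closed-form diffusion/equilibrium checks,
determinism, rigid-body integrity, and the autocorrelation-time estimator."""

import numpy as np
import pytest

from telocompact.builder import bend_mean_cos, build_protein, sample_wlc_positions
from telocompact.dynamics import (
    IntegratorConfig,
    Simulation,
    bd_step,
    end_to_end_autocorrelation,
    run,
)
from telocompact.forcefield import BeadKind, DNAChain, ForceField, SystemState


def _bead_chain(n, spacing=1000.0):
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n) * spacing
    return DNAChain(pos, np.ones(n, dtype=np.int8), bond_r0=spacing)


def _free_ff(spacing=1000.0):
    return ForceField(k_bond=0.0, k_bend=0.0, bond_r0=spacing, epsilon_lj=np.zeros((6, 6))).without_electrostatics()


def test_zero_force_no_noise_leaves_state_unchanged():
    chain = _bead_chain(4)
    state = SystemState(chain, [], 0.0)
    cfg = IntegratorConfig(thermal_noise_on=False, seed=0)
    new = bd_step(state, _free_ff(), cfg)
    assert np.array_equal(new.dna.positions, state.dna.positions)


def test_free_diffusion_msd():
    """MSD over disjoint intervals matches 6 D t (Einstein relation)."""
    n = 256
    chain = _bead_chain(n)
    sim = Simulation(SystemState(chain, [], 0.0), _free_ff(), IntegratorConfig(seed=11))
    start = sim.dna_pos.copy()
    interval, n_int = 1000, 12
    disp2 = []
    prev = start
    for _ in range(n_int):
        sim.step(interval)
        disp2.append(np.sum((sim.dna_pos - prev) ** 2, axis=1))
        prev = sim.dna_pos.copy()
    msd = float(np.mean(disp2))
    expected = 6.0 * sim.cfg.D_dt * interval
    assert msd == pytest.approx(expected, rel=0.05)


def test_harmonic_trap_variance():
    """Long-run positional variance in a k=10 trap equals kBT/k within 5%."""
    n = 64
    chain = _bead_chain(n)
    anchors = chain.positions.copy()
    tethers = [(i, anchors[i], 10.0) for i in range(n)]
    sim = Simulation(SystemState(chain, [], 0.0), _free_ff(), IntegratorConfig(seed=5), tethers=tethers)
    sim.step(20_000)  # equilibrate
    samples = []
    for _ in range(400):
        sim.step(100)
        samples.append(sim.dna_pos - anchors)
    var = np.concatenate(samples).ravel().var()
    assert var == pytest.approx(0.1, rel=0.05)


def test_identical_seed_bit_identical():
    ff = ForceField()
    rng = np.random.default_rng(4)
    pos = sample_wlc_positions(60, ff.k_bend, rng)
    chain = DNAChain(pos, np.full(60, BeadKind.DNA_SPECIFIC_HIGH, dtype=np.int8))
    state = SystemState(chain, [build_protein(pos[20] + [0, 0, 5.0])], 0.0)
    t1 = run(state, ff, IntegratorConfig(seed=9, n_steps=4000), frame_interval=1000)
    t2 = run(state, ff, IntegratorConfig(seed=9, n_steps=4000), frame_interval=500)
    assert np.array_equal(t1.frames[-1].dna.positions, t2.frames[-1].dna.positions)
    assert np.array_equal(t1.frames[-1].proteins[0].orientation, t2.frames[-1].proteins[0].orientation)


def test_zero_steps_returns_initial_frame_only():
    chain = _bead_chain(5)
    traj = run(SystemState(chain, [], 0.0), _free_ff(), IntegratorConfig(seed=0, n_steps=0))
    assert traj.n_frames == 1


def test_noiseless_dynamics_descends_energy():
    """Overdamped noise-free propagation is gradient descent: the total
    energy is non-increasing frame to frame."""
    ff = ForceField()
    rng = np.random.default_rng(2)
    pos = sample_wlc_positions(10, 5.0, rng)  # floppier than default: real forces
    chain = DNAChain(pos, np.full(10, BeadKind.DNA_SPECIFIC_HIGH, dtype=np.int8))
    sim = Simulation(SystemState(chain, [], 0.0), ff, IntegratorConfig(seed=0, thermal_noise_on=False))
    energies = [sim.compute_forces()]
    for _ in range(20):
        sim.step(200)
        energies.append(sim.compute_forces())
    diffs = np.diff(energies)
    assert np.all(diffs <= 1e-9)


def test_rigid_bodies_preserve_site_geometry():
    ff = ForceField()
    prots = [build_protein(np.array([0.0, 0, 20.0])), build_protein(np.array([30.0, 0, 20.0]))]
    chain = _bead_chain(2, spacing=1.0)
    chain.bond_r0 = 1.0
    sim = Simulation(SystemState(chain, prots, 0.0), ff, IntegratorConfig(seed=3))
    ref = prots[0].site_offsets
    d_ref = np.linalg.norm(ref[:, None, :] - ref[None, :, :], axis=-1)
    sim.step(100_000)
    snap = sim.snapshot()
    for p in snap.proteins:
        sp = p.site_positions() - p.center
        d = np.linalg.norm(sp[:, None, :] - sp[None, :, :], axis=-1)
        assert np.max(np.abs(d - d_ref)) < 1e-9
        assert abs(np.linalg.norm(p.orientation) - 1.0) < 1e-12


def test_periodic_wrap_preserves_minimum_image_distances():
    ff = ForceField()
    rng = np.random.default_rng(8)
    pos = rng.uniform(-30, 80, size=(20, 3))  # deliberately out of the box
    pos[:, 0] = np.arange(20) * 1.0 + pos[:, 0] * 0.01
    chain = DNAChain(np.cumsum(rng.normal(0, 0.3, (20, 3)), axis=0) + pos * 0, np.ones(20, dtype=np.int8))
    chain.positions[:, 0] += np.arange(20)
    chain.positions += 47.0  # shift some beads past the box edge
    state = SystemState(chain, [], box_side=50.0)
    wrapped = state.wrapped()
    box = 50.0

    def min_image(a, b):
        d = a - b
        d -= box * np.round(d / box)
        return np.linalg.norm(d)

    for i in range(0, 20, 3):
        for j in range(i + 1, 20, 5):
            d0 = min_image(state.dna.positions[i], state.dna.positions[j])
            d1 = min_image(wrapped.dna.positions[i], wrapped.dna.positions[j])
            assert d0 == pytest.approx(d1, abs=1e-9)


def test_unstable_step_aborts_with_diagnostics():
    from telocompact.dynamics import UnstableStepError

    # beads 0 and 2 (non-bonded) in deep core overlap
    pos = np.array([[0.0, 0, 0], [0.15, 5.0, 0], [0.3, 0, 0]])
    chain = DNAChain(pos, np.ones(3, dtype=np.int8), bond_r0=1.0)
    ff = ForceField(k_bond=0.0, k_bend=0.0)
    sim = Simulation(SystemState(chain, [], 0.0), ff, IntegratorConfig(seed=0))
    with pytest.raises(UnstableStepError):
        sim.step(5)


def test_bending_equilibrium_matches_boltzmann_quadrature():
    """BD sampling of a 3-bead joint reproduces the Boltzmann angle
    distribution (KS distance < 0.02 against the quadrature CDF)."""
    from scipy import integrate

    ff = ForceField(epsilon_lj=np.zeros((6, 6))).without_electrostatics()
    pos = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
    chain = DNAChain(pos, np.ones(3, dtype=np.int8))
    sim = Simulation(SystemState(chain, [], 0.0), ff, IntegratorConfig(seed=17))
    sim.step(20_000)
    thetas = []
    for _ in range(100_000):
        sim.step(20)
        p = sim.dna_pos
        v1, v2 = p[1] - p[0], p[2] - p[1]
        u = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        thetas.append(np.arccos(np.clip(u, -1, 1)))
    grid = np.linspace(0, np.pi, 4001)
    dens = np.sin(grid) * np.exp(-0.5 * ff.k_bend * grid**2)
    cdf = integrate.cumulative_trapezoid(dens, grid, initial=0.0)
    cdf /= cdf[-1]
    ks = np.max(np.abs(np.interp(np.sort(thetas), grid, cdf) - np.arange(1, len(thetas) + 1) / len(thetas)))
    assert ks < 0.02


class TestAutocorrelation:
    def test_white_noise_tau_about_one_frame(self):
        rng = np.random.default_rng(0)
        tau, se = end_to_end_autocorrelation(rng.normal(size=5000), frame_dt_ns=1.0)
        assert tau < 2.0

    def test_ar1_recovery(self):
        rng = np.random.default_rng(1)
        tau_true = 100.0
        phi = np.exp(-1.0 / tau_true)
        x = np.empty(60_000)
        x[0] = 0.0
        noise = rng.normal(size=len(x))
        for i in range(1, len(x)):
            x[i] = phi * x[i - 1] + noise[i]
        tau, _ = end_to_end_autocorrelation(x)
        assert tau == pytest.approx(tau_true, rel=0.10)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            end_to_end_autocorrelation(np.full(100, 3.0))
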