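"""Pivot Monte Carlo equilibration of a protein-free DNA chain.

Brownian dynamics relaxes the long-wavelength bending modes of a
semiflexible chain on 1e7+ step timescales (mode relaxation ~ 1/q^4), far
beyond desk scale, so BD alone cannot redraw the global realization a chain
started from.  Pivot moves rotate a whole chain tail around a bead and mix
those global modes in a few thousand accepted moves; the BD sampler then
only needs to supply the local (bond, short-wavelength) fluctuations.

The chain is treated with rigid 1-nm bonds during MC (rotations preserve
bond lengths exactly); the harmonic-bond fluctuations re-equilibrate within
a few hundred BD steps afterwards.
"""

from __future__ import annotations

import numpy as np

from .forcefield import ForceField

__all__ = ["chain_nonbonded_cross_energy", "pivot_mc_equilibrate"]


def _bend_at(pos: np.ndarray, j: int, k_bend: float) -> float:
    v1 = pos[j] - pos[j - 1]
    v2 = pos[j + 1] - pos[j]
    u = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    th = np.arccos(np.clip(u, -1.0, 1.0))
    return 0.5 * k_bend * th * th


def chain_nonbonded_cross_energy(
    head: np.ndarray,
    tail: np.ndarray,
    ff: ForceField,
    q_per_bead: float,
    head_offset: int = 0,
) -> float:
    """Non-bonded (LJ + Yukawa) energy between two chain segments.

    ``head`` holds beads [0..p], ``tail`` beads [p+1..]; the bonded pair
    (p, p+1) across the junction is excluded.  Used for pivot-move energy
    differences: intra-segment energies are invariant under the rigid
    rotation, only these cross terms change.
    """
    if len(head) == 0 or len(tail) == 0:
        return 0.0
    from scipy.spatial.distance import cdist

    r = cdist(head, tail)
    r[-1, 0] = np.inf  # bonded pair (p, p+1) across the junction
    energy = 0.0
    eps = ff.epsilon_lj[1, 1]  # DNA-DNA steric term
    lj_cut = ff.r_cut_lj + ff.delta_nm
    in_lj = r < lj_cut
    if np.any(in_lj):
        sc6 = (ff.sigma / ff.r_cut_lj) ** 6
        shift = 4.0 * eps * (sc6 * sc6 - sc6)
        x = np.maximum(r[in_lj] - ff.delta_nm, 0.05)
        sr6 = (ff.sigma / x) ** 6
        energy += float(np.sum(4.0 * eps * (sr6 * sr6 - sr6) - shift))
    qq = q_per_bead * q_per_bead
    if qq != 0.0:
        in_yk = r < ff.r_cut_yukawa
        ryk = r[in_yk]
        energy += float(np.sum(ff.coulomb_scale * qq * np.exp(-ff.kappa * ryk) / ryk))
    return energy


def pivot_mc_equilibrate(
    positions: np.ndarray,
    ff: ForceField,
    n_moves: int,
    rng: np.random.Generator,
    q_per_bead: float | None = None,
    angle_sd: float = 0.7,
) -> np.ndarray:
    """Equilibrate a chain configuration with Metropolis pivot moves.

    Each move rotates the tail beyond a uniformly chosen pivot bead by a
    Gaussian random angle about a random axis, and is accepted with the
    Metropolis rule on the bending energy at the pivot joint plus the
    non-bonded cross energy between head and tail.  Returns the new
    configuration (the input is not modified).
    """
    pos = positions.copy()
    n = len(pos)
    if q_per_bead is None:
        q_per_bead = float(ff.charge_by_kind[1])  # high-affinity DNA bead
    for _ in range(n_moves):
        p = int(rng.integers(1, n - 1))
        ax = rng.normal(size=3)
        ax /= np.linalg.norm(ax)
        ang = rng.normal(0.0, angle_sd)
        c, s = np.cos(ang), np.sin(ang)
        K = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]])
        R = np.eye(3) + s * K + (1 - c) * (K @ K)
        head = pos[: p + 1]
        tail_new = (pos[p + 1 :] - pos[p]) @ R.T + pos[p]
        de = 0.0
        if ff.k_bend > 0:
            new = np.vstack([pos[p - 1 : p + 1], tail_new[:1]])
            de += _bend_at(new, 1, ff.k_bend) - _bend_at(pos, p, ff.k_bend)
        de += chain_nonbonded_cross_energy(head, tail_new, ff, q_per_bead)
        de -= chain_nonbonded_cross_energy(head, pos[p + 1 :], ff, q_per_bead)
        if de <= 0 or rng.random() < np.exp(-de):
            pos[p + 1 :] = tail_new
    return pos
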