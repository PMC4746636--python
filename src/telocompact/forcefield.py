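"""Domain types and energy terms of the coarse-grained TRF2/DNA model.

DNA is a bead-spring chain (1-nm beads, -1.4 e/nm effective charge after
Manning condensation, harmonic bonds and bending).  TRF2 is a rigid body
carrying a neutral specific DNA-binding (Myb-type) site, neutral
dimerization (TRFH) sites, and positively charged basic sites (+2.1 e per
1-nm site bead).  Non-bonded pairs interact through a diameter-shifted,
truncated Lennard-Jones potential (steric for most pairs, attractive for
Myb-DNA and dimerization-site pairs) and, for charged pairs, a Yukawa
(Debye-Hueckel) potential.

Units: lengths in nm, energies in kBT, charges in elementary charges.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .electrostatics import coulomb_scale_kBT_nm

__all__ = [
    "BeadKind",
    "ForceField",
    "DNAChain",
    "ProteinBody",
    "SystemState",
    "shifted_lj",
    "yukawa",
    "yukawa_force",
    "bond_energy",
    "bend_energy",
    "total_energy",
    "default_epsilon_table",
]


class BeadKind(enum.IntEnum):
    """Bead species of the model.

    DNA kinds differ only in the specific-binding strength of their region;
    MYB_SITE and DIMER_SITE are neutral protein interaction sites, BASIC_SITE
    is the positively charged basic-domain site, CORE is the steric center of
    the rigid protein body.
    """

    DNA_SPECIFIC_LOW = 0
    DNA_SPECIFIC_HIGH = 1
    MYB_SITE = 2
    DIMER_SITE = 3
    BASIC_SITE = 4
    CORE = 5


N_KINDS = len(BeadKind)

#: bead diameter (nm); every bead of the model is 1 nm wide
BEAD_DIAMETER_NM = 1.0
#: DNA linear charge density after Manning condensation (e/nm), 1 bead per nm
DNA_CHARGE_PER_BEAD = -1.4
#: basic-domain linear charge density (e/nm) mapped onto 1-nm site beads
BASIC_CHARGE_PER_BEAD = +2.1

#: steric-only LJ depth: small enough that the attractive well is negligible
EPS_STERIC = 0.1


def default_epsilon_table(
    eps_specific: float = 5.0,
    eps_dimer: float = 6.0,
    low_affinity_fraction: float = 0.25,
    eps_steric: float = EPS_STERIC,
) -> np.ndarray:
    """Symmetric (kind x kind) table of LJ well depths in kBT.

    Only two interactions are deliberately attractive: the specific
    DNA-binding site against DNA (scaled down by ``low_affinity_fraction`` on
    the flanking low-affinity regions) and dimerization sites against each
    other.  Everything else is excluded volume only.  The attractive depths
    are calibration outputs (see :func:`telocompact.builder.calibrate_epsilons`):
    they are set so that compaction proceeds at full strength but ceases when
    any one protein interaction is halved.
    """
    eps = np.full((N_KINDS, N_KINDS), eps_steric, dtype=float)
    eps[BeadKind.MYB_SITE, BeadKind.DNA_SPECIFIC_HIGH] = eps_specific
    eps[BeadKind.DNA_SPECIFIC_HIGH, BeadKind.MYB_SITE] = eps_specific
    eps[BeadKind.MYB_SITE, BeadKind.DNA_SPECIFIC_LOW] = eps_specific * low_affinity_fraction
    eps[BeadKind.DNA_SPECIFIC_LOW, BeadKind.MYB_SITE] = eps_specific * low_affinity_fraction
    eps[BeadKind.DIMER_SITE, BeadKind.DIMER_SITE] = eps_dimer
    return eps


def default_charge_table() -> np.ndarray:
    """Charge (e) per bead kind."""
    q = np.zeros(N_KINDS, dtype=float)
    q[BeadKind.DNA_SPECIFIC_LOW] = DNA_CHARGE_PER_BEAD
    q[BeadKind.DNA_SPECIFIC_HIGH] = DNA_CHARGE_PER_BEAD
    q[BeadKind.BASIC_SITE] = BASIC_CHARGE_PER_BEAD
    return q


@dataclass
class ForceField:
    """All pair/bond/angle parameters of the model.

    ``r_cut_lj`` follows the convention of the diameter-shifted potential:
    the LJ term is truncated (and energy-shifted to zero) at separation
    ``r_cut_lj + delta_nm``.  ``k_bend`` defaults to the value calibrated to a
    46.1-nm persistence length (see ``builder.calibrate_bending``).
    """

    sigma: float = 1.0
    delta_nm: float = 0.0
    r_cut_lj: float = 2.0
    epsilon_lj: np.ndarray = field(default_factory=default_epsilon_table)
    kappa: float = 1.0 / 3.0
    r_cut_yukawa: float = 10.0
    coulomb_scale: float = field(default_factory=coulomb_scale_kBT_nm)
    k_bond: float = 330.0
    bond_r0: float = BEAD_DIAMETER_NM
    k_bend: float = 45.93224120562637  # calibrated: lp = 46.1 nm at b = 1 nm
    charge_by_kind: np.ndarray = field(default_factory=default_charge_table)
    affinity_scale_low_vs_high: float = 0.25

    def __post_init__(self) -> None:
        self.epsilon_lj = np.asarray(self.epsilon_lj, dtype=float)
        self.charge_by_kind = np.asarray(self.charge_by_kind, dtype=float)
        if self.epsilon_lj.shape != (N_KINDS, N_KINDS):
            raise ValueError(f"epsilon_lj must be {N_KINDS}x{N_KINDS}")
        if not np.allclose(self.epsilon_lj, self.epsilon_lj.T):
            raise ValueError("epsilon_lj must be symmetric in the kind pair")
        if min(self.r_cut_lj, self.r_cut_yukawa) <= 0:
            raise ValueError("cutoffs must be positive")
        if self.k_bond < 0 or self.k_bend < 0:
            raise ValueError("k_bond and k_bend must be non-negative")
        if self.coulomb_scale <= 0:
            raise ValueError("coulomb_scale must be positive")

    # -- convenience modifiers used by calibration and knockdown runs -------

    def without_electrostatics(self) -> "ForceField":
        """Copy with all charges zeroed (used for bending calibration)."""
        return replace(self, charge_by_kind=np.zeros_like(self.charge_by_kind))

    def scaled(
        self,
        specific: float = 1.0,
        dimer: float = 1.0,
        basic_electrostatics: float = 1.0,
    ) -> "ForceField":
        """Copy with the three protein interactions scaled.

        ``basic_electrostatics`` scales the basic-site charge, i.e. the
        strength of the nonspecific electrostatic protein-DNA attraction.
        """
        eps = self.epsilon_lj.copy()
        for dna in (BeadKind.DNA_SPECIFIC_LOW, BeadKind.DNA_SPECIFIC_HIGH):
            eps[BeadKind.MYB_SITE, dna] *= specific
            eps[dna, BeadKind.MYB_SITE] *= specific
        eps[BeadKind.DIMER_SITE, BeadKind.DIMER_SITE] *= dimer
        q = self.charge_by_kind.copy()
        q[BeadKind.BASIC_SITE] *= basic_electrostatics
        return replace(self, epsilon_lj=eps, charge_by_kind=q)

    @property
    def max_cutoff(self) -> float:
        return max(self.r_cut_lj + self.delta_nm, self.r_cut_yukawa)


# ---------------------------------------------------------------------------
# pair / bond / angle potentials (scalar reference implementations)
# ---------------------------------------------------------------------------


def shifted_lj(
    r: float,
    eps: float,
    sigma: float = 1.0,
    delta: float = 0.0,
    r_cut: float = 2.0,
) -> tuple[float, float]:
    """Diameter-shifted, truncated Lennard-Jones potential.

    V(r) = 4 eps [ (sigma/(r-delta))^12 - (sigma/(r-delta))^6 ] - V_cut for
    r < r_cut + delta and 0 beyond; the energy shift makes V continuous at
    truncation.  Returns (energy in kBT, radial force magnitude in kBT/nm,
    positive = repulsive).

    Raises for r <= delta (overlapping hard cores, diverging potential).
    """
    if eps < 0 or sigma <= 0 or r_cut <= 0:
        raise ValueError("eps, sigma, r_cut must be non-negative/positive")
    if r <= delta:
        raise ValueError(f"core overlap: r = {r} <= delta = {delta}")
    if r >= r_cut + delta:
        return 0.0, 0.0
    x = r - delta
    sr6 = (sigma / x) ** 6
    sc6 = (sigma / r_cut) ** 6
    energy = 4.0 * eps * (sr6 * sr6 - sr6) - 4.0 * eps * (sc6 * sc6 - sc6)
    # force = -dV/dr; positive magnitude pushes the pair apart
    force = 4.0 * eps * (12.0 * sr6 * sr6 - 6.0 * sr6) / x
    return energy, force


def yukawa(
    r: float,
    q1: float,
    q2: float,
    kappa: float = 1.0 / 3.0,
    coulomb_scale: float | None = None,
    r_cut: float = 10.0,
) -> float:
    """Screened Coulomb (Yukawa / Debye-Hueckel) pair energy in kBT.

    E(r) = coulomb_scale * q1 * q2 * exp(-kappa r) / r, truncated at r_cut.
    The sign follows the charge product: DNA-DNA pairs repel, DNA against the
    positive basic site attract.
    """
    if r <= 0:
        raise ValueError("coincident charges: r must be positive")
    if q1 == 0.0 or q2 == 0.0 or r >= r_cut:
        return 0.0
    if coulomb_scale is None:
        coulomb_scale = coulomb_scale_kBT_nm()
    return coulomb_scale * q1 * q2 * np.exp(-kappa * r) / r


def yukawa_force(
    r: float,
    q1: float,
    q2: float,
    kappa: float = 1.0 / 3.0,
    coulomb_scale: float | None = None,
    r_cut: float = 10.0,
) -> float:
    """Radial force -dE/dr of the Yukawa pair energy (positive = repulsive)."""
    if r <= 0:
        raise ValueError("coincident charges: r must be positive")
    if q1 == 0.0 or q2 == 0.0 or r >= r_cut:
        return 0.0
    if coulomb_scale is None:
        coulomb_scale = coulomb_scale_kBT_nm()
    pref = coulomb_scale * q1 * q2 * np.exp(-kappa * r)
    return pref * (1.0 / r**2 + kappa / r)


def bond_energy(r: float, r0: float = 1.0, k_bond: float = 330.0) -> float:
    """Harmonic bond energy 0.5 k (r - r0)^2 in kBT."""
    if r < 0:
        raise ValueError("bond length must be non-negative")
    return 0.5 * k_bond * (r - r0) ** 2


def bend_energy(theta: float, k_bend: float) -> float:
    """Harmonic bending energy 0.5 k theta^2 in kBT.

    ``theta`` is the deviation from collinearity of three consecutive beads,
    in radians (0 = straight chain).
    """
    return 0.5 * k_bend * theta * theta


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class DNAChain:
    """A bead-spring DNA molecule at 1 bead / nm.

    ``region_layout`` is a list of (start, end, kind) half-open index ranges
    partitioning the chain into specific-affinity classes; the default
    telomere-mimicking substrate is 200 nm low-affinity flank + 1000 nm
    high-affinity core + 200 nm flank.
    """

    positions: np.ndarray
    kinds: np.ndarray
    bond_r0: float = BEAD_DIAMETER_NM
    region_layout: list[tuple[int, int, BeadKind]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.kinds = np.asarray(self.kinds, dtype=np.int8)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if len(self.kinds) != len(self.positions):
            raise ValueError("kinds and positions length mismatch")
        if self.region_layout:
            covered = sorted((s, e) for s, e, _ in self.region_layout)
            if covered[0][0] != 0 or covered[-1][1] != self.n_beads or any(
                covered[i][1] != covered[i + 1][0] for i in range(len(covered) - 1)
            ):
                raise ValueError("region_layout must partition the chain")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def length_nm(self) -> float:
        return float(self.n_beads * self.bond_r0)

    def copy(self) -> "DNAChain":
        return DNAChain(self.positions.copy(), self.kinds.copy(), self.bond_r0, list(self.region_layout))


# cube with face-centered interaction centers: sites at the six face centers
# of a 1-nm cube around the steric core.  One specific (Myb) site, three
# dimerization sites (limiting the dimer coordination number to three), two
# charged basic sites.  The basic sites flank the Myb face so that the
# charged domain assists the specific attachment to the same DNA (its
# occupancy/sliding role); the face opposite Myb is a dimerization site, so
# a DNA-bound protein always presents a dimer face to a second DNA strand -
# DNA-DNA bridges are therefore built from protein dimers.
CUBE_FACE_OFFSETS = 0.5 * np.array(
    [
        [+1.0, 0.0, 0.0],  # MYB
        [0.0, +1.0, 0.0],  # BASIC
        [0.0, -1.0, 0.0],  # BASIC
        [0.0, 0.0, +1.0],  # DIMER
        [-1.0, 0.0, 0.0],  # DIMER (anti-Myb face)
        [0.0, 0.0, -1.0],  # DIMER
    ]
)
CUBE_FACE_KINDS = np.array(
    [
        BeadKind.MYB_SITE,
        BeadKind.BASIC_SITE,
        BeadKind.BASIC_SITE,
        BeadKind.DIMER_SITE,
        BeadKind.DIMER_SITE,
        BeadKind.DIMER_SITE,
    ],
    dtype=np.int8,
)

# pentahedron variant: square pyramid, sites on the apex and the four base
# corners ("9 edges and 5 corners" counting the base diagonals as edges of
# the triangulated base).  Apex = Myb site; two opposite base corners carry
# dimerization sites, the other two the basic sites.
_PENT_BASE = 0.5
PENTAHEDRON_OFFSETS = np.array(
    [
        [0.0, 0.0, 0.7],  # apex MYB
        [+_PENT_BASE, +_PENT_BASE, -0.3],  # DIMER
        [-_PENT_BASE, -_PENT_BASE, -0.3],  # DIMER
        [+_PENT_BASE, -_PENT_BASE, -0.3],  # BASIC
        [-_PENT_BASE, +_PENT_BASE, -0.3],  # BASIC
    ]
)
PENTAHEDRON_KINDS = np.array(
    [
        BeadKind.MYB_SITE,
        BeadKind.DIMER_SITE,
        BeadKind.DIMER_SITE,
        BeadKind.BASIC_SITE,
        BeadKind.BASIC_SITE,
    ],
    dtype=np.int8,
)


class ProteinGeometry(enum.Enum):
    CUBE_FACE_CENTERED = "cube_face_centered"
    PENTAHEDRON = "pentahedron"


@dataclass
class ProteinBody:
    """Rigid three-domain protein: steric core plus interaction sites.

    ``site_offsets`` are body-frame coordinates; world-frame positions follow
    from the center and the unit quaternion ``orientation`` (scalar-first).
    """

    center: np.ndarray
    orientation: np.ndarray
    site_offsets: np.ndarray
    site_kinds: np.ndarray
    geometry_tag: ProteinGeometry = ProteinGeometry.CUBE_FACE_CENTERED

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        self.site_offsets = np.asarray(self.site_offsets, dtype=float)
        self.site_kinds = np.asarray(self.site_kinds, dtype=np.int8)
        norm = np.linalg.norm(self.orientation)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("orientation quaternion must be normalized to 1 within 1e-9")
        kinds = list(self.site_kinds)
        if kinds.count(BeadKind.MYB_SITE) != 1:
            raise ValueError("protein must carry exactly one MYB_SITE")
        if kinds.count(BeadKind.DIMER_SITE) < 1 or kinds.count(BeadKind.BASIC_SITE) < 1:
            raise ValueError("protein must carry at least one DIMER_SITE and one BASIC_SITE")

    @property
    def n_sites(self) -> int:
        return len(self.site_offsets)

    def rotation_matrix(self) -> np.ndarray:
        from .rigid import quat_to_matrix

        return quat_to_matrix(self.orientation)

    def site_positions(self) -> np.ndarray:
        """World-frame positions of the interaction sites."""
        return self.center + self.site_offsets @ self.rotation_matrix().T

    def copy(self) -> "ProteinBody":
        return ProteinBody(
            self.center.copy(),
            self.orientation.copy(),
            self.site_offsets,
            self.site_kinds,
            self.geometry_tag,
        )


@dataclass
class SystemState:
    """Full configuration: one DNA chain plus rigid proteins in a periodic box.

    Coordinates are stored unwrapped (so chain contours and cluster analyses
    stay continuous); all pair interactions use the minimum-image convention
    with box side ``box_side``.  ``box_side = 0`` means open boundaries.
    """

    dna: DNAChain
    proteins: list[ProteinBody] = field(default_factory=list)
    box_side: float = 0.0
    time_ns: float = 0.0

    def copy(self) -> "SystemState":
        return SystemState(
            self.dna.copy(), [p.copy() for p in self.proteins], self.box_side, self.time_ns
        )

    def wrapped(self) -> "SystemState":
        """Copy with all coordinates wrapped into [0, box_side)."""
        s = self.copy()
        if self.box_side > 0:
            s.dna.positions %= self.box_side
            for p in s.proteins:
                p.center %= self.box_side
        return s


# ---------------------------------------------------------------------------
# total energy
# ---------------------------------------------------------------------------


def _minimum_image(d: np.ndarray, box: float) -> np.ndarray:
    if box > 0:
        d = d - box * np.round(d / box)
    return d


def gather_particles(state: SystemState) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pack DNA beads and protein core+site beads into flat arrays.

    Returns (positions, kinds, body_id, dna_index) where body_id is -1 for
    DNA beads and the protein index otherwise, and dna_index is the chain
    index for DNA beads and -1 otherwise.
    """
    n_dna = state.dna.n_beads
    pos = [state.dna.positions]
    kinds = [state.dna.kinds]
    body = [np.full(n_dna, -1, dtype=np.int32)]
    dna_index = [np.arange(n_dna, dtype=np.int32)]
    for b, p in enumerate(state.proteins):
        sp = p.site_positions()
        pos.append(np.vstack([p.center[None, :], sp]))
        kinds.append(np.concatenate([[BeadKind.CORE], p.site_kinds]).astype(np.int8))
        body.append(np.full(1 + p.n_sites, b, dtype=np.int32))
        dna_index.append(np.full(1 + p.n_sites, -1, dtype=np.int32))
    return (
        np.ascontiguousarray(np.vstack(pos)),
        np.concatenate(kinds),
        np.concatenate(body),
        np.concatenate(dna_index),
    )


def pair_energy(
    pos: np.ndarray,
    kinds: np.ndarray,
    body_id: np.ndarray,
    dna_index: np.ndarray,
    ff: ForceField,
    box: float,
    pairs: np.ndarray | None = None,
) -> float:
    """Non-bonded energy over the given pair list (or all pairs if None).

    Excludes intra-body pairs and DNA bonded neighbors.  This is the plain
    numpy reference used to validate the fast neighbor-list kernel.
    """
    n = len(pos)
    if pairs is None:
        ii, jj = np.triu_indices(n, k=1)
    else:
        ii, jj = pairs[:, 0], pairs[:, 1]
    keep = ~((body_id[ii] >= 0) & (body_id[ii] == body_id[jj]))
    bonded = (dna_index[ii] >= 0) & (dna_index[jj] >= 0) & (np.abs(dna_index[ii] - dna_index[jj]) == 1)
    keep &= ~bonded
    ii, jj = ii[keep], jj[keep]
    d = _minimum_image(pos[ii] - pos[jj], box)
    r = np.linalg.norm(d, axis=1)
    energy = 0.0
    eps = ff.epsilon_lj[kinds[ii], kinds[jj]]
    in_lj = r < ff.r_cut_lj + ff.delta_nm
    if np.any(r[in_lj] <= ff.delta_nm):
        raise FloatingPointError("core overlap in pair energy (r <= delta)")
    x = r[in_lj] - ff.delta_nm
    sr6 = (ff.sigma / x) ** 6
    sc6 = (ff.sigma / ff.r_cut_lj) ** 6
    energy += float(np.sum(4.0 * eps[in_lj] * (sr6 * sr6 - sr6 - (sc6 * sc6 - sc6))))
    q = ff.charge_by_kind[kinds[ii]] * ff.charge_by_kind[kinds[jj]]
    in_yk = (r < ff.r_cut_yukawa) & (q != 0.0)
    energy += float(
        np.sum(ff.coulomb_scale * q[in_yk] * np.exp(-ff.kappa * r[in_yk]) / r[in_yk])
    )
    return energy


def total_energy(state: SystemState, ff: ForceField, pairs: np.ndarray | None = None) -> float:
    """Sum of bond + bend + shifted-LJ + Yukawa energies of the state in kBT.

    ``pairs`` may supply a precomputed candidate pair list (e.g. from a
    neighbor search); by default all pairs are evaluated.
    """
    pos, kinds, body_id, dna_index = gather_particles(state)
    energy = pair_energy(pos, kinds, body_id, dna_index, ff, state.box_side, pairs)
    # bonds and bends along the DNA chain
    p = state.dna.positions
    if len(p) >= 2:
        bonds = np.linalg.norm(np.diff(p, axis=0), axis=1)
        energy += float(0.5 * ff.k_bond * np.sum((bonds - ff.bond_r0) ** 2))
    if len(p) >= 3 and ff.k_bend > 0:
        v1 = p[1:-1] - p[:-2]
        v2 = p[2:] - p[1:-1]
        cosang = np.sum(v1 * v2, axis=1) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        theta = np.arccos(np.clip(cosang, -1.0, 1.0))
        energy += float(0.5 * ff.k_bend * np.sum(theta**2))
    if not np.isfinite(energy):
        raise FloatingPointError("non-finite total energy: core overlap or broken state")
    return energy
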