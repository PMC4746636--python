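"""Measurement protocols: reproducible, desk-scale simulation recipes that
tests, the analysis scripts and the acceptance checks all share.

Each protocol fixes its problem size and run length as a package-level
choice (documented in the methods note) and exposes the seed as the only
free input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .builder import build_dna, init_system, sample_wlc_positions
from .dynamics import IntegratorConfig, Simulation, Trajectory, run
from .forcefield import BeadKind, DNAChain, ForceField, SystemState
from .observables import (
    PersistenceFit,
    StageThresholds,
    persistence_length,
)

__all__ = [
    "measure_persistence_length",
    "paired_persistence_lengths",
    "CompactionRunResult",
    "scaled_down_state",
    "compaction_run",
    "compaction_protocol",
    "occupancy_run",
]


def measure_persistence_length(
    ff: ForceField,
    seed: int = 1,
    n_beads: int = 200,
    n_configs: int = 192,
    mc_moves: int = 6_000,
    bd_equil_steps: int = 2_000,
    bd_sample_steps: int = 6_000,
    frame_every: int = 2_000,
    s_min: int = 2,
    s_max: int = 25,
) -> PersistenceFit:
    """Tangent-correlation persistence length of a protein-free chain from
    equilibrated Brownian-dynamics sampling.

    The long-wavelength bending modes of a 200-bead chain relax on ~1e7 BD
    steps (mode time ~ 1/q^4), so a single trajectory never redraws its
    global realization at desk scale.  The protocol therefore averages over
    ``n_configs`` independent configurations: each is drawn from the
    worm-like-chain angle distribution, equilibrated globally with pivot
    Monte Carlo under the full Hamiltonian (which supplies the non-bonded /
    electrostatic corrections the WLC draw lacks), relaxed briefly with BD
    (restoring the harmonic-bond ensemble), and then sampled with BD.
    Tangent correlations are pooled over all configurations and frames and
    fitted as exp(-s/lp) over s in [s_min, s_max] nm.
    """
    from .mcsampler import pivot_mc_equilibrate

    frames: list[np.ndarray] = []
    for r in range(n_configs):
        rng = np.random.default_rng([seed, r, 7919])
        pos = sample_wlc_positions(n_beads, ff.k_bend, rng)
        if mc_moves > 0:
            pos = pivot_mc_equilibrate(pos, ff, mc_moves, rng)
        chain = DNAChain(pos, np.full(n_beads, BeadKind.DNA_SPECIFIC_HIGH, dtype=np.int8))
        cfg = IntegratorConfig(seed=seed * 100_000 + r)
        sim = Simulation(SystemState(chain, [], 0.0), ff, cfg)
        sim.step(bd_equil_steps)
        for _ in range(max(bd_sample_steps // frame_every, 1)):
            sim.step(frame_every)
            frames.append(sim.dna_pos.copy())
    return persistence_length(frames, s_min=s_min, s_max=s_max, seed=seed)


def paired_persistence_lengths(
    ff: ForceField | None = None,
    seed: int = 1,
    **kwargs,
) -> tuple[PersistenceFit, PersistenceFit]:
    """(uncharged, charged) persistence lengths of the DNA model.

    Same protocol, same seeds, electrostatics off/on; each condition is
    equilibrated under its own Hamiltonian.
    """
    ff = ff or ForceField()
    fit_off = measure_persistence_length(ff.without_electrostatics(), seed=seed, **kwargs)
    fit_on = measure_persistence_length(ff, seed=seed, **kwargs)
    return fit_off, fit_on


# ---------------------------------------------------------------------------
# scaled-down compaction protocol
# ---------------------------------------------------------------------------

#: scaled-down system: 150-nm DNA / 15 proteins at the reference 2.7 uM
#: (geometrically similar to the full 1400-nm / 200-protein system; sized so
#: the full 4-condition x 5-seed sensitivity verification is desk-scale)
SCALED_DNA_NM = 150.0
SCALED_FLANK_NM = 21.0  # keeps the reference ~1:5:1 low/high/low layout ratio
SCALED_N_PROTEINS = 15
SCALED_BOX_NM = 500.0 * (SCALED_N_PROTEINS / 200.0) ** (1.0 / 3.0)  # ~210.9 nm
SCALED_LOOP_BEADS = 90
#: initial strand separation at the crossover: wide enough that the strands
#: are not yet in DNA-DNA contact, narrow enough that the capture dimer's
#: Myb faces sit at the edge of their attraction range (a dimer bridge
#: spans ~5.3 nm once both Myb anchors engage)
SCALED_GAP_NM = 6.4
#: compaction verdict threshold on the final compacted DNA length (nm)
SCALED_COMPACTION_THRESHOLD_NM = 12.0


@dataclass
class CompactionRunResult:
    trajectory: Trajectory
    compacted_series: list[float]
    final_compacted_nm: float
    threshold_nm: float
    compacted: bool
    thresholds: StageThresholds = field(default_factory=StageThresholds)


def _roll_for_dimer(side: np.ndarray, toward: np.ndarray, n_grid: int = 180) -> float:
    """Roll angle about the Myb axis that points one of the lateral dimer
    faces (body +z / -z) closest to ``toward``."""
    from scipy.spatial.transform import Rotation

    side = side / np.linalg.norm(side)
    toward = toward / np.linalg.norm(toward)
    base, _ = Rotation.align_vectors(side[None, :], np.array([[1.0, 0.0, 0.0]]))
    best, best_val = 0.0, -np.inf
    for roll in np.linspace(0.0, 2.0 * np.pi, n_grid, endpoint=False):
        rot = Rotation.from_rotvec(roll * side) * base
        for body_face in (np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, -1.0])):
            val = float(np.dot(rot.apply(body_face), toward))
            if val > best_val:
                best_val, best = val, roll
    return best


def _roll_for_basic(side: np.ndarray, tangent: np.ndarray, n_grid: int = 180) -> float:
    """Roll angle about the Myb axis that lays the two basic faces (body
    +y / -y) along the chain tangent, engaging the charged domain with the
    neighboring DNA beads (the grip-assist orientation)."""
    from scipy.spatial.transform import Rotation

    side = side / np.linalg.norm(side)
    tangent = tangent / np.linalg.norm(tangent)
    base, _ = Rotation.align_vectors(side[None, :], np.array([[1.0, 0.0, 0.0]]))
    best, best_val = 0.0, -np.inf
    for roll in np.linspace(0.0, np.pi, n_grid, endpoint=False):
        rot = Rotation.from_rotvec(roll * side) * base
        val = abs(float(np.dot(rot.apply(np.array([0.0, 1.0, 0.0])), tangent)))
        if val > best_val:
            best_val, best = val, roll
    return best


def _bound_protein_at_bead(
    dna_pos: np.ndarray, bead: int, side: np.ndarray, roll: float = 0.0
) -> "tuple[np.ndarray, np.ndarray]":
    """Center and orientation of a protein Myb-bound at a chain bead.

    ``side`` is the world direction from the protein toward the bead (the
    Myb face); ``roll`` rotates the body around that axis, which sets where
    the dimerization and basic faces point.
    """
    from scipy.spatial.transform import Rotation

    side = side / np.linalg.norm(side)
    center = dna_pos[bead] - 1.62 * side  # Myb site then sits 1.12 nm off
    # rotation taking body +x (Myb) to `side`, then roll about it
    rot, _ = Rotation.align_vectors(side[None, :], np.array([[1.0, 0.0, 0.0]]))
    rot = Rotation.from_rotvec(roll * side) * rot
    q = rot.as_quat()  # scipy: (x, y, z, w)
    return center, np.array([q[3], q[0], q[1], q[2]])


def scaled_down_state(seed: int, ff: ForceField | None = None, n_proteins: int = SCALED_N_PROTEINS) -> SystemState:
    """Initial state of the scaled-down compaction system.

    Two desk-scale shortcuts set the starting point mid-pathway; everything
    the sensitivity rule probes (dimerization on DNA, crossover capture,
    zipping, collapse - or their failure) happens downstream of both:

    * The DNA starts as a low-strain crossed loop: the configuration of the
      rare thermal fluctuation that initiates compaction, with two distal
      segments a protein-length apart.  Waiting for this crossover to form
      spontaneously is diffusion-limited on the full system's millisecond
      timescale and unreachable at desk scale.
    * Proteins start Myb-bound at well-separated chain beads (the
      monomer-loaded state that bulk binding produces anyway, see
      :func:`occupancy_run`), two of them a few beads apart near - but not
      at - the crossover, with their basic faces toward the distal strand.
      They are not dimerized at t = 0.

    An uncaptured crossing simply diffuses apart, so knockdown arms are
    free to fail.
    """
    from .builder import build_protein, crossed_loop_positions
    from .forcefield import DNAChain

    ff = ff or ForceField()
    dna = build_dna(SCALED_DNA_NM, SCALED_FLANK_NM, SCALED_DNA_NM - 2 * SCALED_FLANK_NM)
    n = dna.n_beads
    raw = crossed_loop_positions(n, loop_beads=SCALED_LOOP_BEADS, crossing_gap=SCALED_GAP_NM)
    shift = SCALED_BOX_NM / 2.0 - raw.mean(axis=0)
    pos = raw + shift
    dna.positions[:] = pos
    state = SystemState(dna, [], SCALED_BOX_NM, 0.0)

    arm = (n - SCALED_LOOP_BEADS) // 2
    crossing = (arm, arm + SCALED_LOOP_BEADS)  # bead indices at the crossover
    apex = arm + SCALED_LOOP_BEADS // 2
    rng = np.random.default_rng([seed, 20513])
    up = np.array([0.0, 0.0, 1.0])
    occupied: list[int] = []
    proteins = []

    # the capture unit: a free (not DNA-bound) protein dimer floating in
    # the crossover gap, each Myb face toward its strand at the edge of its
    # attraction range.  Whether the unit converts the crossover into a
    # stable dimer-stabilized bridge before diffusing away or falling
    # apart - and whether that bridge then holds and recruits - is decided
    # by the interaction strengths, not by construction.
    s2v = np.sqrt(0.5)
    q_up = np.array([s2v, 0.0, -s2v, 0.0])  # body +x (Myb) -> world +z
    q_down = np.array([s2v, 0.0, s2v, 0.0])  # body +x (Myb) -> world -z
    mid = 0.5 * (pos[crossing[0]] + pos[crossing[1]])
    proteins.append(build_protein(mid + np.array([0.0, 0.0, +1.05]), q_up))
    proteins.append(build_protein(mid + np.array([0.0, 0.0, -1.05]), q_down))
    occupied += [crossing[0], crossing[1]]

    # a pair of bound monomers near the loop apex with lateral dimer faces
    # toward each other, just outside the dimer cutoff: the "dimerization
    # on DNA" event of the pathway
    tangent_apex = pos[apex + 1] - pos[apex - 1]
    tangent_apex /= np.linalg.norm(tangent_apex)
    for bead, toward in ((apex - 1, tangent_apex), (apex + 2, -tangent_apex)):
        center, q = _bound_protein_at_bead(pos, bead, up, roll=_roll_for_dimer(up, toward))
        # nudge the pair along the chain so the facing dimer sites start
        # ~1.6 nm apart (inside attraction, outside the dimer cutoff)
        center = center + 0.2 * (toward if bead < apex else toward)
        proteins.append(build_protein(center, q))
        occupied.append(bead)

    # remaining proteins: Myb-bound monomers at random beads, >= 5 beads
    # apart and >= 6 beads from the crossover, random side, basic-assist roll
    candidates = [
        b
        for b in range(2, n - 2)
        if min(abs(b - crossing[0]), abs(b - crossing[1])) >= 12
    ]
    rng.shuffle(candidates)
    for b in candidates:
        if len(proteins) >= n_proteins:
            break
        if any(abs(b - o) < 5 for o in occupied):
            continue
        tangent = pos[min(b + 1, n - 1)] - pos[max(b - 1, 0)]
        tangent /= np.linalg.norm(tangent)
        perp = np.cross(tangent, rng.normal(size=3))
        if np.linalg.norm(perp) < 1e-6:
            continue
        perp /= np.linalg.norm(perp)
        center, q = _bound_protein_at_bead(pos, b, perp, roll=_roll_for_basic(perp, tangent))
        proteins.append(build_protein(center, q))
        occupied.append(b)
    state.proteins = proteins
    return state


def compaction_run(
    ff: ForceField,
    seed: int,
    n_steps: int = 200_000,
    frame_every: int = 100,
    thresholds: StageThresholds | None = None,
) -> CompactionRunResult:
    """One scaled-down compaction trajectory with the compaction verdict.

    The verdict is final compacted DNA length (nm of DNA inside the largest
    protein cluster) exceeding one third of the chain.
    """
    from .observables import globule_and_loop

    th = thresholds or StageThresholds()
    state = scaled_down_state(seed, ff)
    cfg = IntegratorConfig(seed=seed, n_steps=n_steps)
    traj = run(state, ff, cfg, frame_interval=frame_every)
    # the verdict series only needs ~100 points; stage analyses re-visit
    # the stored frames at full resolution when they need to
    stride = max(len(traj.frames) // 100, 1)
    picked = traj.frames[::stride]
    if traj.frames[-1] is not picked[-1]:
        picked = picked + [traj.frames[-1]]
    series = []
    for frame in picked:
        _, compacted, _ = globule_and_loop(frame, th.cluster_cutoff, th.bind_cutoff, th.l_min)
        series.append(compacted)
    final = float(np.mean(series[-3:])) if len(series) >= 3 else series[-1]
    return CompactionRunResult(
        trajectory=traj,
        compacted_series=series,
        final_compacted_nm=final,
        threshold_nm=SCALED_COMPACTION_THRESHOLD_NM,
        compacted=final > SCALED_COMPACTION_THRESHOLD_NM,
        thresholds=th,
    )


def compaction_protocol(ff: ForceField, seed: int) -> tuple[float, float]:
    """Callable signature used by :func:`telocompact.builder.calibrate_epsilons`:
    returns (final compacted length, threshold)."""
    res = compaction_run(ff, seed)
    return res.final_compacted_nm, res.threshold_nm


def occupancy_run(
    ff: ForceField,
    seed: int,
    dna_nm: float = 100.0,
    n_proteins: int = 10,
    n_steps: int = 120_000,
    frame_every: int = 2_000,
    bind_cutoff: float = 1.5,
) -> float:
    """Mean DNA occupancy over the final third of a monomer-release run.

    Half the proteins start Myb-bound in pairs three beads apart on a
    relaxed coil; the other half float free in a shell around the chain.
    With dimerization enabled the bound pairs dimerize and present free
    dimerization faces that recruit the floating proteins onto the DNA
    (and hold them there with the avidity of multiple anchors); with it
    disabled the same initial condition gains coverage only through direct
    binding.  The paired on/off comparison isolates the occupancy gain
    that protein dimerization provides.
    """
    from .builder import build_protein
    from .observables import occupancy

    n = int(round(dna_nm))
    dna = build_dna(dna_nm, 0.0, dna_nm)
    box = 500.0 * (n_proteins / 200.0) ** (1.0 / 3.0)
    rng = np.random.default_rng([seed, 515])
    pos = sample_wlc_positions(n, ff.k_bend, rng)
    pos = pos - pos.mean(axis=0) + box / 2.0
    dna.positions[:] = pos
    state = SystemState(dna, [], box, 0.0)
    # bound pairs at beads (b, b+3), lateral dimer faces toward each other
    n_pairs = max(n_proteins // 4, 1)
    anchors = np.linspace(5, n - 9, n_pairs).astype(int)
    up = np.array([0.0, 0.0, 1.0])
    for b in anchors:
        tangent = pos[b + 2] - pos[b - 1]
        tangent /= np.linalg.norm(tangent)
        side = np.cross(tangent, up)
        side /= max(np.linalg.norm(side), 1e-9)
        for bead, toward in ((int(b), tangent), (int(b) + 3, -tangent)):
            center, q = _bound_protein_at_bead(pos, bead, side, roll=_roll_for_dimer(side, toward))
            state.proteins.append(build_protein(center, q))
    # the rest float free in a shell around the chain
    from .rigid import random_quaternion

    placed = [pos] + [p.center[None, :] for p in state.proteins]
    while len(state.proteins) < n_proteins:
        bead = pos[rng.integers(0, n)]
        offset = rng.normal(size=3)
        offset *= rng.uniform(4.0, 15.0) / np.linalg.norm(offset)
        center = bead + offset
        if np.min(np.linalg.norm(np.vstack(placed) - center, axis=1)) > 2.0:
            state.proteins.append(build_protein(center, random_quaternion(rng)))
            placed.append(center[None, :])
    cfg = IntegratorConfig(seed=seed, n_steps=n_steps)
    traj = run(state, ff, cfg, frame_interval=frame_every)
    occ = [occupancy(f, bind_cutoff) for f in traj.frames]
    third = 2 * len(occ) // 3
    return float(np.mean(occ[third:]))
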