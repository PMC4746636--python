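"""Brownian-dynamics propagation of the mixed DNA + rigid-protein system.

Overdamped (position-Langevin) integration: each DNA bead moves by
``(D/kBT) F dt + sqrt(2 D dt) xi`` per step; each rigid protein translates
with the net force on its beads and rotates with the net torque about its
center (small-angle quaternion increment, renormalized every step).  The
thermal kick uses the Leimkuhler-Matthews (BAOAB-limit) average of the
current and previous step's Gaussian variates, which removes the leading
O(dt) configurational sampling bias of the plain Euler-Maruyama scheme at
identical cost - important here because the 330 kBT/nm^2 bonds put the
stiffest mode at D k dt ~ 0.07 per step.

Randomness is counter-based: normal deviates are drawn in fixed-size step
blocks from a Philox generator keyed by the seed with the block index as
counter, so trajectories are bit-reproducible and independent of observer
frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from ._kernels import compute_forces
from .forcefield import BeadKind, ForceField, SystemState, gather_particles

__all__ = [
    "IntegratorConfig",
    "Trajectory",
    "Simulation",
    "UnstableStepError",
    "bd_step",
    "run",
    "free_protein_fraction",
    "depletion_stop",
    "end_to_end_autocorrelation",
]

_NOISE_BLOCK = 256  # steps of noise drawn per Philox counter increment


class UnstableStepError(RuntimeError):
    """A particle moved more than half a bead diameter in one step."""


@dataclass
class IntegratorConfig:
    """Brownian-dynamics integrator parameters.

    The nominal physical step is 50 ps; the absolute time label is set by
    matching end-to-end fluctuation autocorrelation times to experiment (see
    :func:`end_to_end_autocorrelation`) and is therefore nominal.  Drags are
    in kBT.ps/nm^2 (translation, per bead) and kBT.ps (rotation, per body);
    the defaults put the per-step bead mobility at D*dt = 2e-4 nm^2, safely
    inside the stability limit of the 330 kBT/nm^2 bonds.
    """

    dt_ps: float = 50.0
    n_steps: int = 0
    drag_translation: float = 2.5e5
    drag_rotation: float = 2.5e5
    seed: int = 0
    thermal_noise_on: bool = True
    neighbor_every: int = 20
    neighbor_skin: float = 1.5
    max_step_nm: float = 0.5  # abort threshold (0.5 * sigma)

    def __post_init__(self) -> None:
        if self.dt_ps <= 0 or self.drag_translation <= 0 or self.drag_rotation <= 0:
            raise ValueError("dt and drags must be positive")

    @property
    def D_dt(self) -> float:
        """Translational diffusion step D*dt in nm^2 (kBT = 1)."""
        return self.dt_ps / self.drag_translation

    @property
    def Dr_dt(self) -> float:
        """Rotational diffusion step D_r*dt in rad^2."""
        return self.dt_ps / self.drag_rotation


@dataclass
class Trajectory:
    """Time-ordered system snapshots plus per-frame observable records."""

    frames: list[SystemState]
    times_ns: list[float]
    frame_interval: int
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def _quats_to_matrices(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    m = np.empty((len(q), 3, 3))
    m[:, 0, 0] = 1 - 2 * (y * y + z * z)
    m[:, 0, 1] = 2 * (x * y - w * z)
    m[:, 0, 2] = 2 * (x * z + w * y)
    m[:, 1, 0] = 2 * (x * y + w * z)
    m[:, 1, 1] = 1 - 2 * (x * x + z * z)
    m[:, 1, 2] = 2 * (y * z - w * x)
    m[:, 2, 0] = 2 * (x * z - w * y)
    m[:, 2, 1] = 2 * (y * z + w * x)
    m[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return m


class Simulation:
    """Packed, propagatable view of a :class:`SystemState`.

    Construction copies the state; :meth:`snapshot` converts back.  Optional
    ``tethers`` is a list of ``(dna_bead_index, anchor_xyz, k)`` harmonic
    restraints (used e.g. for trap validation runs).
    """

    def __init__(
        self,
        state: SystemState,
        ff: ForceField,
        cfg: IntegratorConfig,
        tethers: Sequence[tuple[int, np.ndarray, float]] | None = None,
    ):
        self.ff = ff
        self.cfg = cfg
        self.box = float(state.box_side)
        self.n_dna = state.dna.n_beads
        self.bond_r0 = state.dna.bond_r0
        self.dna_kinds = state.dna.kinds.copy()
        self.dna_pos = state.dna.positions.copy()
        self.region_layout = list(state.dna.region_layout)
        self._template_proteins = [p.copy() for p in state.proteins]
        self.n_prot = len(state.proteins)
        if self.n_prot:
            ns = {p.n_sites for p in state.proteins}
            if len(ns) != 1:
                raise ValueError("all proteins must share one site geometry")
            self.n_sites = ns.pop()
            self.site_offsets = state.proteins[0].site_offsets.copy()
            self.site_kinds = state.proteins[0].site_kinds.copy()
            self.centers = np.array([p.center for p in state.proteins])
            self.quats = np.array([p.orientation for p in state.proteins])
        else:
            self.n_sites = 0
            self.site_offsets = np.zeros((0, 3))
            self.site_kinds = np.zeros(0, dtype=np.int8)
            self.centers = np.zeros((0, 3))
            self.quats = np.zeros((0, 4))

        # flat particle arrays: [dna beads][per protein: core, sites...]
        per = 1 + self.n_sites
        self.n_total = self.n_dna + self.n_prot * per
        self.kinds = np.empty(self.n_total, dtype=np.int8)
        self.kinds[: self.n_dna] = self.dna_kinds
        body_id = np.full(self.n_total, -1, dtype=np.int32)
        dna_index = np.full(self.n_total, -1, dtype=np.int32)
        dna_index[: self.n_dna] = np.arange(self.n_dna)
        for b in range(self.n_prot):
            s = self.n_dna + b * per
            self.kinds[s] = BeadKind.CORE
            self.kinds[s + 1 : s + per] = self.site_kinds
            body_id[s : s + per] = b
        self.body_id = body_id
        self.dna_index = dna_index
        self.charges = ff.charge_by_kind[self.kinds]
        self.pos = np.empty((self.n_total, 3))
        self.forces = np.zeros_like(self.pos)

        self.bond_i = np.arange(self.n_dna - 1, dtype=np.int32) if self.n_dna > 1 else np.zeros(0, np.int32)
        self.bond_j = self.bond_i + 1
        self.ang_mid = (
            np.arange(1, self.n_dna - 1, dtype=np.int32) if self.n_dna > 2 else np.zeros(0, np.int32)
        )
        if tethers:
            self.teth_idx = np.array([t[0] for t in tethers], dtype=np.int32)
            self.teth_anchor = np.array([t[1] for t in tethers], dtype=float)
            self.teth_k = np.array([t[2] for t in tethers], dtype=float)
        else:
            self.teth_idx = np.zeros(0, np.int32)
            self.teth_anchor = np.zeros((0, 3))
            self.teth_k = np.zeros(0)

        self.step_count = 0
        self.time_ns = state.time_ns
        self._pairs_age = None
        self._noise = None
        self._noise_block_index = -1
        self._lm_prev: np.ndarray | None = None
        self._update_site_positions()
        self._rebuild_neighbors()

    # -- internals ----------------------------------------------------------

    def _update_site_positions(self) -> None:
        self.pos[: self.n_dna] = self.dna_pos
        if self.n_prot:
            per = 1 + self.n_sites
            rot = _quats_to_matrices(self.quats)  # (P,3,3)
            sites = self.centers[:, None, :] + np.einsum("pij,sj->psi", rot, self.site_offsets)
            block = self.pos[self.n_dna :].reshape(self.n_prot, per, 3)
            block[:, 0, :] = self.centers
            block[:, 1:, :] = sites

    def _filter_exclusions(self, pairs: np.ndarray) -> np.ndarray:
        if not len(pairs):
            return pairs
        ii, jj = pairs[:, 0], pairs[:, 1]
        same_body = (self.body_id[ii] >= 0) & (self.body_id[ii] == self.body_id[jj])
        bonded = (
            (self.dna_index[ii] >= 0)
            & (self.dna_index[jj] >= 0)
            & (np.abs(self.dna_index[ii] - self.dna_index[jj]) == 1)
        )
        return pairs[~(same_body | bonded)]

    def _rebuild_neighbors(self) -> None:
        """Two-tier neighbor list: a short-range list over all particles (LJ
        reach) plus a long-range list over charged particles only (Yukawa
        reach); charged-charged pairs are kept only in the long list."""
        skin = self.cfg.neighbor_skin
        if self.box > 0:
            wrapped = np.mod(self.pos, self.box)
            wrapped[wrapped >= self.box] = 0.0  # cKDTree needs strictly < box
        else:
            wrapped = self.pos
        box_arg = self.box if self.box > 0 else None
        tree = cKDTree(wrapped, boxsize=box_arg)
        short = tree.query_pairs(
            self.ff.r_cut_lj + self.ff.delta_nm + skin, output_type="ndarray"
        ).astype(np.int32)
        charged_mask = self.charges != 0.0
        if charged_mask.any():
            cidx = np.flatnonzero(charged_mask).astype(np.int32)
            ctree = cKDTree(wrapped[cidx], boxsize=box_arg)
            longp = ctree.query_pairs(
                self.ff.r_cut_yukawa + skin, output_type="ndarray"
            ).astype(np.int32)
            longp = cidx[longp]
            if len(short):
                both_charged = charged_mask[short[:, 0]] & charged_mask[short[:, 1]]
                short = short[~both_charged]
            pairs = np.vstack([short, longp]) if len(short) else longp
        else:
            pairs = short
        pairs = self._filter_exclusions(pairs)
        self.pi = np.ascontiguousarray(pairs[:, 0]) if len(pairs) else np.zeros(0, np.int32)
        self.pj = np.ascontiguousarray(pairs[:, 1]) if len(pairs) else np.zeros(0, np.int32)

    @property
    def _ndof(self) -> int:
        return 3 * self.n_dna + 6 * self.n_prot

    def _noise_block(self, block_index: int) -> np.ndarray:
        gen = np.random.Generator(
            np.random.Philox(key=self.cfg.seed & 0x7FFFFFFF, counter=[0, 0, 0, block_index])
        )
        return gen.standard_normal((_NOISE_BLOCK, self._ndof))

    def _take_noise(self, start_step: int, k: int) -> np.ndarray:
        """Standard-normal rows for steps [start_step, start_step + k).

        Rows are indexed by absolute step through a counter-based Philox
        stream, so the draw pattern is independent of chunking and observer
        frequency.
        """
        out = np.empty((k, self._ndof))
        filled = 0
        while filled < k:
            step = start_step + filled
            block_index, row = divmod(step, _NOISE_BLOCK)
            if self._noise is None or self._noise_block_index != block_index:
                self._noise = self._noise_block(block_index)
                self._noise_block_index = block_index
            take = min(_NOISE_BLOCK - row, k - filled)
            out[filled : filled + take] = self._noise[row : row + take]
            filled += take
        return out

    def compute_forces(self) -> float:
        """Evaluate all forces at the current configuration; returns energy."""
        ff = self.ff
        return compute_forces(
            self.pos,
            self.pi,
            self.pj,
            self.kinds,
            ff.epsilon_lj,
            self.charges,
            ff.sigma,
            ff.delta_nm,
            ff.r_cut_lj,
            ff.kappa,
            ff.coulomb_scale,
            ff.r_cut_yukawa,
            self.box,
            self.bond_i,
            self.bond_j,
            ff.bond_r0,
            ff.k_bond,
            self.ang_mid,
            ff.k_bend,
            self.teth_idx,
            self.teth_anchor,
            self.teth_k,
            self.forces,
        )

    def step(self, n: int = 1) -> None:
        """Advance ``n`` BD steps (numba-compiled inner loop)."""
        from ._kernels import step_block

        cfg = self.cfg
        ff = self.ff
        D_dt = cfg.D_dt
        Dr_dt = cfg.Dr_dt
        sig_t = np.sqrt(2.0 * D_dt) if cfg.thermal_noise_on else 0.0
        sig_r = np.sqrt(2.0 * Dr_dt) if cfg.thermal_noise_on else 0.0
        remaining = n
        while remaining > 0:
            if self._pairs_age is None or self._pairs_age >= cfg.neighbor_every:
                self._update_site_positions()
                self._rebuild_neighbors()
                self._pairs_age = 0
            n_inner = min(cfg.neighbor_every - self._pairs_age, remaining)
            if cfg.thermal_noise_on:
                noise = self._take_noise(self.step_count, n_inner)
                if self._lm_prev is None:
                    # first step: full-amplitude kick (no previous variate)
                    self._lm_prev = noise[0].copy()
            else:
                noise = np.zeros((n_inner, self._ndof))
            if self._lm_prev is None:
                self._lm_prev = np.zeros(self._ndof)
            worst = step_block(
                self.pos,
                self.dna_pos,
                self.centers,
                self.quats,
                self.site_offsets,
                self.n_dna,
                self.pi,
                self.pj,
                self.kinds,
                ff.epsilon_lj,
                self.charges,
                ff.sigma,
                ff.delta_nm,
                ff.r_cut_lj,
                ff.kappa,
                ff.coulomb_scale,
                ff.r_cut_yukawa,
                self.box,
                self.bond_i,
                self.bond_j,
                ff.bond_r0,
                ff.k_bond,
                self.ang_mid,
                ff.k_bend,
                self.teth_idx,
                self.teth_anchor,
                self.teth_k,
                self.forces,
                noise,
                self._lm_prev,
                D_dt,
                Dr_dt,
                sig_t,
                sig_r,
                cfg.max_step_nm,
                cfg.thermal_noise_on,
            )
            if worst > cfg.max_step_nm:
                raise UnstableStepError(
                    f"deterministic displacement {worst:.3g} nm > {cfg.max_step_nm} nm near "
                    f"step {self.step_count}: reduce dt or fix overlapping cores"
                )
            self.step_count += n_inner
            self._pairs_age += n_inner
            self.time_ns += n_inner * cfg.dt_ps * 1e-3
            remaining -= n_inner
        self._update_site_positions()

    def snapshot(self) -> SystemState:
        """Current configuration as a standalone :class:`SystemState`."""
        from .forcefield import DNAChain, ProteinBody

        dna = DNAChain(self.dna_pos.copy(), self.dna_kinds.copy(), self.bond_r0, list(self.region_layout))
        prots = []
        for b, tmpl in enumerate(self._template_proteins):
            prots.append(
                ProteinBody(
                    self.centers[b].copy(),
                    self.quats[b] / np.linalg.norm(self.quats[b]),
                    tmpl.site_offsets,
                    tmpl.site_kinds,
                    tmpl.geometry_tag,
                )
            )
        return SystemState(dna, prots, self.box, self.time_ns)


def bd_step(state: SystemState, ff: ForceField, cfg: IntegratorConfig) -> SystemState:
    """Advance the state by a single BD step (convenience wrapper).

    For long runs use :class:`Simulation` or :func:`run` directly; this
    wrapper re-packs the state every call.
    """
    sim = Simulation(state, ff, cfg)
    sim.step(1)
    return sim.snapshot()


def free_protein_fraction(state: SystemState, bind_cutoff: float = 1.5) -> float:
    """Fraction of proteins with no DNA bead within ``bind_cutoff`` of any site."""
    if not state.proteins:
        return 0.0
    from .observables import _site_positions_by_protein

    tree = cKDTree(state.dna.positions)
    free = 0
    for sites in _site_positions_by_protein(state):
        d, _ = tree.query(sites, k=1)
        if np.min(d) > bind_cutoff:
            free += 1
    return free / len(state.proteins)


def depletion_stop(threshold: float = 0.05, bind_cutoff: float = 1.5) -> Callable[[SystemState], bool]:
    """Stopping predicate: fire when < ``threshold`` of proteins remain unbound.

    Mirrors the rule of running until the box is depleted of free proteins so
    no further recruitment is likely.
    """

    def _stop(state: SystemState) -> bool:
        return free_protein_fraction(state, bind_cutoff) < threshold

    return _stop


def run(
    state: SystemState,
    ff: ForceField,
    cfg: IntegratorConfig,
    observers: Sequence[Callable[[int, SystemState], None]] | None = None,
    frame_interval: int = 1000,
    stop_when: Callable[[SystemState], bool] | None = None,
    stop_check_every: int = 10_000,
) -> Trajectory:
    """Propagate ``cfg.n_steps`` BD steps, storing a frame every
    ``frame_interval`` steps (plus the initial frame).

    ``observers`` are called as ``obs(step, frame)`` at every stored frame;
    because noise is counter-based they cannot perturb the trajectory.
    ``stop_when`` is checked every ``stop_check_every`` steps and ends the run
    early (the depletion rule by default lives in :func:`depletion_stop`).
    """
    sim = Simulation(state, ff, cfg)
    frames = [sim.snapshot()]
    times = [sim.time_ns]
    observers = list(observers or [])
    for obs in observers:
        obs(0, frames[0])
    done = 0
    next_stop_check = stop_check_every
    while done < cfg.n_steps:
        chunk = min(frame_interval, cfg.n_steps - done)
        sim.step(chunk)
        done += chunk
        snap = sim.snapshot()
        frames.append(snap)
        times.append(sim.time_ns)
        for obs in observers:
            obs(done, snap)
        if stop_when is not None and done >= next_stop_check:
            next_stop_check += stop_check_every
            if stop_when(snap):
                break
    meta = {
        "seed": cfg.seed,
        "dt_ps": cfg.dt_ps,
        "n_steps_run": done,
        "frame_interval": frame_interval,
    }
    return Trajectory(frames, times, frame_interval, meta)


def end_to_end_autocorrelation(
    series: np.ndarray,
    frame_dt_ns: float = 1.0,
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """Autocorrelation time of an end-to-end distance series.

    Fits an exponential to the normalized autocorrelation function of the
    mean-removed series (log-linear fit over lags where the ACF stays above
    0.05) and returns ``(tau, bootstrap_se)`` in the units of ``frame_dt_ns``
    per frame.  This is the quantity used to anchor the nominal simulation
    time scale against experimentally known DNA relaxation times.

    Raises ``ValueError`` for a constant series and ``RuntimeError`` when the
    correlation does not decay (insufficient sampling).
    """
    from statsmodels.tsa.stattools import acf as _acf

    x = np.asarray(series, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 frames")
    if np.std(x) == 0:
        raise ValueError("zero-variance series: autocorrelation undefined")

    def _fit_tau(y: np.ndarray) -> float:
        nlags = min(len(y) // 2, 2000)
        a = _acf(y, nlags=nlags, fft=True)
        mask = a > 0.05
        stop = np.argmin(mask) if not mask.all() else len(a)
        stop = max(stop, 2)
        lags = np.arange(stop)
        slope = np.polyfit(lags, np.log(np.clip(a[:stop], 1e-12, None)), 1)[0]
        if slope >= 0:
            raise RuntimeError("non-decaying autocorrelation: insufficient sampling")
        return -1.0 / slope

    tau = _fit_tau(x)
    if len(x) < 10 * tau:
        raise RuntimeError(
            f"series too short: {len(x)} frames < 10 * tau ({tau:.1f} frames)"
        )
    # circular block bootstrap with blocks of ~5 tau
    rng = np.random.default_rng(seed)
    block = max(int(5 * tau), 5)
    n_blocks = max(len(x) // block, 1)
    taus = []
    for _ in range(n_boot):
        starts = rng.integers(0, len(x), size=n_blocks)
        idx = (starts[:, None] + np.arange(block)[None, :]).ravel() % len(x)
        try:
            taus.append(_fit_tau(x[idx]))
        except RuntimeError:
            continue
    se = float(np.std(taus)) if len(taus) > 2 else float("nan")
    return tau * frame_dt_ns, se * frame_dt_ns
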