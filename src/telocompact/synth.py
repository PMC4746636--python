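"""Synthetic measurement generators.

Everything the analysis pipeline consumes can be generated here with the
statistical structure the analysis assumes: per-complex AFM tables with the
published volume/height mixture structure and the linear volume-vs-compacted-
length relation, DREEM traces with distinct free/bound signal levels and an
enhanced sub-population, and deterministic geometric trajectory fixtures for
the compaction observables.

Default parameters are the published single-molecule statistics, so the
parameter-recovery test suite doubles as a demonstration of the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .afm import AFMTable, DreemTrace
from .electrostatics import NM_PER_BP
from .forcefield import BeadKind, DNAChain, SystemState
from .dynamics import Trajectory

__all__ = [
    "AfmGeneratorParams",
    "gen_afm_table",
    "gen_dreem_traces",
    "gen_fixture_trajectory",
]


@dataclass
class AfmGeneratorParams:
    """Generator settings for per-complex AFM tables.

    Defaults reproduce the published statistics of TRF2-DNA complexes on
    the 1721-nm telomeric substrate: small complexes (dimer/tetramer) draw
    volumes from a two-component Gaussian mixture and heights from a single
    Gaussian; large complexes draw volumes log-uniformly over the published
    range, with contour lengths shortened along V = 1284 + 3.2 L_c (bp).
    Measurement noise levels are chosen so the implied raw-fit R^2 is in
    the published ballpark (~0.5-0.6).
    """

    small_volume_means: tuple[float, float] = (142.3, 266.6)
    small_volume_sds: tuple[float, float] = (93.9, 53.4)
    small_volume_weights: tuple[float, float] = (0.5, 0.5)
    small_height_mean: float = 0.5
    small_height_sd: float = 0.4
    small_contour_mean: float = 1704.0
    small_contour_sd: float = 59.0
    large_volume_range: tuple[float, float] = (520.0, 13359.0)
    large_height_means: tuple[float, float] = (1.3, 2.4)
    large_height_sds: tuple[float, float] = (0.8, 0.4)
    baseline_contour_nm: float = 1721.0
    compaction_intercept: float = 1284.0  # nm^3
    compaction_slope: float = 3.2  # nm^3 per bp
    compacted_noise_bp: float = 150.0
    volume_noise_nm3: float = 2000.0


def gen_afm_table(
    n_small: int = 134,
    n_large: int = 69,
    params: AfmGeneratorParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-complex AFM table with small and large TRF2-DNA complexes."""
    p = params or AfmGeneratorParams()
    rng = np.random.default_rng(seed)
    rows = []
    comp = np.array(p.small_volume_weights) / np.sum(p.small_volume_weights)
    for _ in range(n_small):
        c = rng.choice(2, p=comp)
        vol = -1.0
        while vol <= 0:
            vol = rng.normal(p.small_volume_means[c], p.small_volume_sds[c])
        vol = min(vol, 500.0)  # small complexes by definition
        height = abs(rng.normal(p.small_height_mean, p.small_height_sd))
        contour = max(rng.normal(p.small_contour_mean, p.small_contour_sd), 1.0)
        rows.append((vol, height, contour, "SMALL", 1))
    lo, hi = np.log(p.large_volume_range[0]), np.log(p.large_volume_range[1])
    for _ in range(n_large):
        vol_true = float(np.exp(rng.uniform(lo, hi)))
        c = rng.choice(2)
        height = abs(rng.normal(p.large_height_means[c], p.large_height_sds[c]))
        lc_true = max((vol_true - p.compaction_intercept) / p.compaction_slope, 0.0)
        lc_obs = lc_true + rng.normal(0.0, p.compacted_noise_bp)
        contour = p.baseline_contour_nm - lc_obs * NM_PER_BP
        if contour <= 0:
            raise ValueError("impossible truncation: compacted length exceeds substrate")
        vol_obs = max(vol_true + rng.normal(0.0, p.volume_noise_nm3), 501.0)
        rows.append((vol_obs, height, contour, "LARGE", 1))
    return AFMTable(
        pd.DataFrame(
            rows,
            columns=[
                "volume_nm3",
                "height_nm",
                "dna_contour_length_nm",
                "size_class",
                "complexes_per_molecule",
            ],
        )
    )


def gen_dreem_traces(
    n: int = 60,
    level_free: float = -1.0,
    level_bound_delta: float = 0.35,
    enhanced_fraction: float = 0.32,
    noise_sd: float = 0.15,
    seed: int = 0,
    samples_per_segment: int = 30,
) -> list[DreemTrace]:
    """Per-complex DREEM traces with an enhanced sub-population.

    Each complex's bound-DNA segment mean sits above the free-DNA level
    with probability ``enhanced_fraction`` and below it otherwise, offset
    by a per-complex magnitude ~ |N(delta, delta/3)|, with i.i.d. Gaussian
    sample noise along the trace.
    """
    if not 0.0 <= enhanced_fraction <= 1.0:
        raise ValueError("enhanced_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    traces = []
    for k in range(n):
        sign = 1.0 if rng.random() < enhanced_fraction else -1.0
        magnitude = abs(rng.normal(level_bound_delta, level_bound_delta / 3.0))
        free = rng.normal(level_free, noise_sd, size=samples_per_segment)
        bound = rng.normal(level_free + sign * magnitude, noise_sd, size=samples_per_segment)
        samples = np.concatenate([free, bound])
        labels = np.array(["DNA_FREE"] * samples_per_segment + ["DNA_BOUND"] * samples_per_segment)
        traces.append(DreemTrace(samples, labels, complex_id=k))
    return traces


# ---------------------------------------------------------------------------
# deterministic geometric trajectory fixtures
# ---------------------------------------------------------------------------


def _chain_state(pos: np.ndarray, proteins=None) -> SystemState:
    n = len(pos)
    chain = DNAChain(pos, np.full(n, BeadKind.DNA_SPECIFIC_HIGH, dtype=np.int8))
    return SystemState(chain, proteins or [], 0.0, 0.0)


def _protein_at(center: np.ndarray) -> "object":
    from .builder import build_protein

    return build_protein(np.asarray(center, dtype=float))


def gen_fixture_trajectory(scenario: str, seed: int = 0) -> Trajectory:
    """Hand-constructed frames with exactly known compaction observables.

    Scenarios:

    * ``free_dna``: straight 200-bead chain, no proteins (stage FREE).
    * ``hairpin``: a V-shaped chain whose arms touch only near the apex,
      with three proteins residing at the junction, one of them bridging
      (stage CROSSOVER_CAPTURED; contacts lie on the anti-diagonal
      i + j = 2 * apex).
    * ``zipped``: a long parallel hairpin ladder bridged by proteins along
      its length (a >= 25-nm register-aligned contact run).
    * ``globule_with_loop``: beads 300-900 collapsed into a protein-rich
      ball with beads 500-559 pushed outside on a protein-free arc (a
      60-nm protruding loop).
    """
    rng = np.random.default_rng(seed)
    if scenario == "free_dna":
        pos = np.zeros((200, 3))
        pos[:, 0] = np.arange(200)
        frames = [_chain_state(pos) for _ in range(3)]
    elif scenario == "hairpin":
        n, apex, theta = 100, 50, np.deg2rad(25)
        pos = np.zeros((n, 3))
        for k in range(1, apex + 1):
            pos[apex - k] = [k * np.cos(theta / 2), +k * np.sin(theta / 2), 0.0]
            if apex + k < n:
                pos[apex + k] = [k * np.cos(theta / 2), -k * np.sin(theta / 2), 0.0]
        # three proteins at the junction; the closest one bridges both arms
        mid = pos[apex] + np.array([3.0, 0.0, 0.0])
        prots = [
            _protein_at(mid + np.array([0.0, 0.0, 1.3])),
            _protein_at(mid + np.array([2.2, 0.0, 1.3])),
            _protein_at(mid + np.array([0.0, 2.2, 1.3])),
        ]
        frames = [_chain_state(pos, prots)]
    elif scenario == "zipped":
        n, arm = 100, 40
        pos = np.zeros((n, 3))
        for k in range(arm):
            pos[k] = [arm - k, 0.0, 0.0]
        # apex: 20 beads looping around
        for j, ang in enumerate(np.linspace(0, np.pi, n - 2 * arm)):
            pos[arm + j] = [-np.sin(ang) * 6.4, 0.0, 3.2 - 3.2 * np.cos(ang) - 3.2 + 1.6]
        for k in range(arm):
            pos[n - arm + k] = [k + 1, 0.0, -3.2]
        pos[:arm, 2] = 0.0
        pos[n - arm :, 2] = -3.2
        from .builder import build_protein

        s2 = np.sqrt(0.5)
        q_up = np.array([s2, 0.0, -s2, 0.0])  # Myb face -> +z (upper strand)
        q_down = np.array([s2, 0.0, s2, 0.0])  # Myb face -> -z (lower strand)
        prots = []
        for x in (6.0, 14.0, 22.0, 30.0):
            prots.append(build_protein(np.array([x, 0.0, -1.62]), q_up.copy()))
            prots.append(build_protein(np.array([x + 2.2, 0.0, -1.58]), q_down.copy()))
        frames = [_chain_state(pos, prots)]
    elif scenario == "globule_with_loop":
        n = 1200
        pos = np.zeros((n, 3))
        # flanks: straight lines leaving the ball
        pos[:300, 0] = -np.arange(300, 0, -1) - 10.0
        pos[900:, 0] = np.arange(n - 900) + 10.0
        # ball: spherical spiral of radius 10 for beads 300..899 minus loop
        ball_beads = [b for b in range(300, 900) if not (500 <= b < 560)]
        t = np.linspace(0, 1, len(ball_beads))
        phi = 20 * np.pi * t
        costh = 2 * t - 1
        sinth = np.sqrt(1 - costh**2)
        radius = 10.0 * (0.3 + 0.7 * t)
        for i, b in enumerate(ball_beads):
            pos[b] = radius[i] * np.array(
                [sinth[i] * np.cos(phi[i]), sinth[i] * np.sin(phi[i]), costh[i]]
            )
        # protruding loop: beads 500..559 on an arc reaching 25 nm out
        ang = np.linspace(0, np.pi, 60)
        for j, b in enumerate(range(500, 560)):
            pos[b] = [25.0 * np.sin(ang[j]), 12.0 + 18.0 * np.sin(ang[j]), 25.0 * np.cos(ang[j]) * 0.2]
        prots = [
            _protein_at(radius[i] * 0.8 * np.array([sinth[i] * np.cos(phi[i] + 0.5), sinth[i] * np.sin(phi[i] + 0.5), costh[i]]))
            for i in range(0, len(ball_beads), 15)
        ]
        frames = [_chain_state(pos, prots)]
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return Trajectory(frames, list(np.arange(len(frames), dtype=float)), 1, {"scenario": scenario})
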