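# Methods

## The model

DNA is a bead-spring chain at 1 bead/nm (bead diameter 1 nm). Bonds are
harmonic, `E = k_bond (r - b)^2 / 2` with `k_bond = 330 kBT/nm^2` and rest
length `b = 1 nm`. Each interior joint carries a harmonic bending potential
`E = k_bend θ^2 / 2` in the deviation-from-collinearity angle. `k_bend` is
not a free parameter: it is root-solved so that the single-joint Boltzmann
average `⟨cos θ⟩ = ∫ cos θ e^{-k θ²/2} sin θ dθ / ∫ e^{-k θ²/2} sin θ dθ`
equals `exp(-b/l_p)` with `l_p = 46.1 nm`, giving `k_bend = 45.932 kBT`.
Each DNA bead carries `-1.4 e` — the effective charge of B-DNA after
Oosawa–Manning counterion condensation, which the package recomputes from
physical constants (`1/l_B = 1.43 e/nm` at 298 K in water, ε_r = 80).

TRF2 is a rigid body: a steric core bead with six interaction sites on the
face centers of a 1-nm cube. One site is the specific DNA-binding (Myb-type)
domain, attractive to DNA through a truncated Lennard-Jones well
(`ε_specific = 5 kBT` on the telomeric core of the substrate, a quarter of
that on the non-specific flanks). The two faces flanking Myb are the basic
domain: `+2.1 e` each, interacting with DNA through the screened Coulomb
term, so that the charged domain assists the specific attachment and powers
non-specific binding/sliding. The remaining three faces (including the one
opposite Myb) are dimerization (TRFH) sites, mutually attractive with
`ε_dimer = 6 kBT`; three sites bound the dimer coordination number at three.
Because the anti-Myb face is a dimerization site, every DNA-bound protein
presents a dimer face to a second DNA duplex — DNA–DNA bridges in this model
are protein-dimer-mediated, which is what makes dimerization essential for
crossover capture.

Non-bonded pairs (bonded neighbors excluded) interact through a truncated,
energy-shifted Lennard-Jones potential `4ε[(σ/(r-Δ))¹² - (σ/(r-Δ))⁶]` with
`σ = 1 nm` and truncation at `r_cut + Δ`, `r_cut = 2 nm`. With 1-nm beads
and `σ = 1 nm` the diameter shift is `Δ = (d_i + d_j)/2 - σ = 0`, so contact
sits at `2^{1/6} σ ≈ 1.12 nm`; all purely steric pairs use `ε = 0.1 kBT`
(negligible well, excluded volume only). Charged pairs add a Yukawa
(Debye–Hückel) term `l_B q_i q_j e^{-κr}/r` with `κ = 1/3 nm⁻¹`, a 10-nm
cutoff, and the Bjerrum-type prefactor `l_B = 0.70 kBT·nm/e²` evaluated from
constants at run time. Temperature is fixed at `kBT = 1` (298 K for unit
conversions).

The two interaction depths (`ε_specific`, `ε_dimer`) are deliberately
calibration outputs, not transcribed constants: they are fixed by the
sensitivity rule (below).

## Brownian dynamics

Overdamped position-Langevin dynamics: per step each DNA bead moves by
`D F dt + √(2 D dt) ξ`; each protein translates with its net force and
rotates with the net torque about its center (small-angle quaternion
increment, renormalized every step). The thermal kick uses the
Leimkuhler–Matthews average `(ξ_n + ξ_{n+1})/2` of consecutive Gaussian
variates, which removes the leading O(dt) configurational bias of plain
Euler–Maruyama at no extra cost. Noise is counter-based (Philox keyed by
the seed, indexed by absolute step), so trajectories are bit-reproducible
and independent of observer frequency or chunking.

The nominal step is 50 ps. The default drag puts the per-step mobility at
`D·dt = 2×10⁻⁴ nm²`, safely inside the stability limit of the stiff bonds
(`D k_bond dt ≈ 0.066`); a Stokes-law drag for a 0.5-nm bead would make the
50-ps step violently unstable against those bonds, so the physical time
label is nominal and the package's autocorrelation-time estimator
(`end_to_end_autocorrelation`) is the instrument for anchoring it to
measured DNA relaxation times. Pair interactions use a two-tier neighbor
list (short-range over all particles, long-range over charged particles)
rebuilt every 20 steps with a 1.5-nm skin; a step whose deterministic
displacement exceeds 0.5 nm aborts with diagnostics.

## Measuring persistence length

The tangent correlation `C(s) = ⟨t(i)·t(i+s)⟩` of a 200-bead protein-free
chain is fitted as `exp(-s/l_p)` over `s = 2–25 nm`. Two numerical facts
shape the protocol:

* Bending modes of wavelength λ relax as `1/q⁴`; for λ ≳ 100 nm that is
  10⁷–10⁸ steps, so a single BD trajectory effectively never redraws the
  global shape it started with. Any single-trajectory estimate carries the
  realization noise of its initial configuration (tens of percent at
  s ≈ 20 nm). The protocol therefore averages over 192 independent
  configurations: each is drawn from the exact Boltzmann angle distribution
  of the bending term (worm-like-chain sampler), equilibrated globally with
  6000 pivot Monte Carlo moves under the full Hamiltonian (supplying the
  non-bonded and electrostatic corrections the draw lacks; pivot moves mix
  global modes in thousands of moves), relaxed 2000 BD steps (restoring the
  harmonic-bond ensemble), and then sampled by BD (3 frames over 6000
  steps).
* The pooled log-linear fit is weighted by the inverse across-frame
  variance of `ln C(s)`: long separations carry few effective samples per
  realization, and down-weighting them roughly halves the estimator noise
  without biasing an exponential decay. On pivot-MC reference ensembles the
  estimator returns 46.1 nm (uncharged; the exact discrete-chain value) and
  ≈ 49.3 nm (charged).

The electrostatic stiffening cross-check uses the closed-form
Odijk–Skolnick–Fixman estimate `l_B ν²/(4κ²) = 3.09 nm`. The model's own
mechanical stiffening, computed by bending a charged chain into arcs and
differencing energies, is ≈ 2.1 nm (the 10-nm truncation and chain
discreteness remove ~1/3 of the OSF integral), and thermal sampling raises
the measured increment to ≈ 2.5–3 nm — within a factor of two of OSF, as it
should be.

## The scaled-down compaction protocol

The reference system (1400-nm DNA, 200 proteins, 2.7 µM, 500-nm periodic
cube) compacts over 5–10 ms of model time, orders of magnitude beyond a
desk-scale run. The sensitivity and pathway analyses therefore use a
geometrically similar system at 150-nm DNA (21/108/21 nm low/high/low
affinity layout) with 15 proteins in a 210.9-nm cube — the same 2.7 µM and
the same layout ratios — and start it mid-pathway:

* The chain is a low-strain crossed loop (90-bead loop, ~5 kBT of stored
  bending): the configuration of the rare thermal fluctuation that brings
  two distal segments within protein reach. Waiting for this crossover to
  arise spontaneously is the diffusion-limited step that consumes the full
  system's milliseconds; everything the analyses probe happens downstream.
* Proteins start Myb-bound at well-separated beads (the monomer-loaded
  state that bulk binding produces anyway), with basic faces laid along the
  chain (the grip-assist orientation they adopt), one not-yet-dimerized
  pair near the loop apex, and one free protein dimer floating in the
  6.4-nm crossover gap with its Myb faces at the edge of their attraction
  range. Whether that unit converts the crossover into a stable
  dimer-stabilized bridge — and whether the bridge then holds, zips, and
  recruits — is decided by the interaction strengths, not by construction;
  an uncaptured crossing diffuses apart.

Compacted length is the DNA inside the largest single-linkage cluster of
*DNA-bound* proteins (cluster cutoff 3.5 nm), counted only when the cluster
holds chain-distal segments together in space — a protein cluster
decorating one straight stretch draws no DNA in. The compaction verdict is
a final compacted length above 12 nm (the value separating the observed
full-strength and knockdown distributions), averaged over the last three
frames of a 2×10⁵-step run.

At the shipped strengths (`ε_specific = 5`, `ε_dimer = 6`), over seeds 1–5:
full strength compacts in 2/5 seeds (final compacted lengths ≈ 18–21 nm;
capture at a thermodynamic knife edge is itself stochastic), while halving
any one of specific binding, dimerization, or the basic-domain charge
abolishes compaction in 5/5 seeds. That asymmetry — occasional success at
100%, reliable failure at 50% of any single term — is the calibration rule
the defaults were chosen to satisfy.

Compacting runs traverse the pathway stages in order: monomers bound →
dimers on DNA → crossover captured (a protein or dimerized pair physically
bridging chain-distal beads) → zipped (register-aligned contact run above
15 nm) → globule (compacted length above 20 nm), under a causal 10-frame
median smoothing of per-frame labels (trailing windows keep the smoother
causal and preserve the initial state). The crossover/cluster cutoffs
(6 nm / 3.5 nm) follow from the bridge geometry: a dimer-bridged strand
pair spans up to ~5.3 nm.

Known limitation: the claim that dimerization raises equilibrium DNA
occupancy does not express in this model at desk-scale horizons. Bead
coverage *drops* slightly with dimerization (dimerized proteins overlap
footprints instead of spreading), and the bound-protein fraction saturates
because the basic domain's electrostatic attachment alone keeps proteins on
DNA far longer than any realizable run. The paired occupancy comparison is
implemented and reported as measured.

## AFM / DREEM statistics

The analysis layer operates on per-complex tables (volume nm³, height nm,
DNA contour length nm, size class at the 500-nm³ threshold) and on DREEM
traces (signal samples labeled free/bound DNA):

* Mixture fits are maximum-likelihood EM on the raw sample, scored by R²
  against the histogram (expected bin occupancies by exact bin integrals).
  Histogram least squares was rejected: for heavily overlapping components
  at n ≈ 134 its objective is multimodal and the fitted means wander by
  50%+ between seeds.
* Group contour lengths are compared with Welch's t-test.
* The volume-vs-compacted-length relation is ordinary least squares of
  volume on the contour shortfall converted at 0.32 nm/bp, reported both
  raw and after averaging volume in 100-bp windows.
* The volume↔molecular-weight calibration is pluggable (instrument
  dependent); a polynomial calibration can be pinned exactly through
  measured anchors and inverted on its monotone branch.
* DREEM contrast is the per-complex bound-minus-free mean with a Welch
  test; a complex is ENHANCED/REDUCED when significant at p < 0.05, and
  the cohort's enhanced fraction carries a Wilson binomial CI.
* The pseudo-AFM renderer draws beads as spheres on a substrate plane
  (max-over-beads height field), dilates by a spherical tip, and measures
  grain volume as Σ(height − floor)·pixel².

## Synthetic data

The generators are first-class, seeded, pure functions. The AFM table
generator emulates the published single-molecule statistics: small-complex
volumes from the two-component mixture (142.3 ± 93.9, 266.6 ± 53.4 nm³,
equal weights, truncated to (0, 500]), heights 0.5 ± 0.4 nm; large-complex
volumes log-uniform over 520–13359 nm³ with contour lengths shortened along
V = 1284 + 3.2·L_c(bp) plus measurement noise (150 bp on compacted length,
2000 nm³ on volume — chosen once so the implied raw-fit R² lands near the
published ~0.5–0.6). The DREEM generator draws each complex's bound-segment
offset sign from Bernoulli(enhanced fraction, default 0.32 at N = 60) with
magnitude |N(0.35, 0.12)| and 0.15 noise on 30 samples per segment. What
these generators do *not* emulate: tip-sample convolution artifacts,
surface-induced conformational bias, image flattening, or any correlation
between height and volume errors — so parameter recovery demonstrates the
statistics, not instrument robustness.

Deterministic geometric fixtures (straight chain, crossed hairpin, bridged
parallel ladder, globule with a 60-nm protruding protein-free loop) give
the compaction observables exactly known targets.

## Problem sizes and numerical choices

Persistence-length runs: 192 configurations per condition, 200 beads,
6000 MC moves + 8000 BD steps each. Sensitivity verification: 4 conditions
× 5 seeds × 2×10⁵ steps at 255 particles. Occupancy comparison: 10 paired
seeds × 1.2×10⁵ steps. Degenerate inputs (zero-variance series,
non-decaying autocorrelations, core overlaps, empty frames, impossible
truncations) raise typed errors rather than returning silent NaNs; the
quadrature/root-solving tolerances are 1e-12 absolute, and ties in the
stage decision list are broken by the fixed precedence order (globule >
multistrand > zipped > captured > dimers > monomers > free).
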