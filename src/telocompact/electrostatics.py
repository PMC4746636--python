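"""Electrostatic scales for DNA in aqueous salt: Bjerrum length, Manning
(Oosawa-Manning) counterion condensation, and the Odijk-Skolnick-Fixman
electrostatic persistence length.

All quantities are evaluated from CODATA physical constants at run time; the
package works in reduced units (lengths in nm, energies in kBT) so the only
conversion constant that enters the force field is the Bjerrum-type Coulomb
prefactor.
"""

from __future__ import annotations

import numpy as np
from scipy import constants as _const

#: relative permittivity of water used throughout the model
WATER_EPS_R = 80.0
#: temperature (K) used for all physical-constant conversions
TEMPERATURE_K = 298.0
#: rise per base pair assumed when converting contour lengths to bp
NM_PER_BP = 0.32
#: bare charge spacing of B-DNA: 2 phosphates per 0.34 nm rise
BDNA_BARE_CHARGE_SPACING_NM = 0.34 / 2.0


def bjerrum_length_nm(eps_r: float = WATER_EPS_R, temperature_K: float = TEMPERATURE_K) -> float:
    """Bjerrum length l_B = e^2 / (4 pi eps_0 eps_r kB T) in nm.

    At 298 K in water (eps_r = 80) this is ~0.70 nm: the distance at which two
    unit charges interact with thermal energy kBT.
    """
    lb_m = _const.e**2 / (4.0 * np.pi * _const.epsilon_0 * eps_r * _const.k * temperature_K)
    return lb_m * 1e9


def coulomb_scale_kBT_nm(eps_r: float = WATER_EPS_R, temperature_K: float = TEMPERATURE_K) -> float:
    """Prefactor of the screened Coulomb pair energy in kBT.nm per e^2.

    E(r) = coulomb_scale * q1 * q2 * exp(-kappa r) / r with q in elementary
    charges and r in nm.  Numerically identical to the Bjerrum length in nm.
    """
    return bjerrum_length_nm(eps_r, temperature_K)


def manning_effective_charge_density(
    bare_spacing_nm: float = BDNA_BARE_CHARGE_SPACING_NM,
    eps_r: float = WATER_EPS_R,
    temperature_K: float = TEMPERATURE_K,
) -> float:
    """Effective linear charge density (e/nm) of a polyelectrolyte after
    Oosawa-Manning counterion condensation.

    For a line charge with bare spacing b the Manning parameter is
    xi = l_B / b.  When xi > 1 counterions condense until the effective
    spacing equals l_B, i.e. the effective density saturates at 1/l_B;
    below the threshold the bare density is kept.  For B-DNA
    (b = 0.17 nm, xi ~ 4.1) this evaluates to ~1.4 e/nm, the charge density
    assigned to the DNA beads of the model.
    """
    if bare_spacing_nm <= 0:
        raise ValueError("bare charge spacing must be positive")
    lb = bjerrum_length_nm(eps_r, temperature_K)
    if lb / bare_spacing_nm > 1.0:
        return 1.0 / lb
    return 1.0 / bare_spacing_nm


def osf_persistence_length_nm(
    charge_density_e_per_nm: float,
    kappa_per_nm: float,
    eps_r: float = WATER_EPS_R,
    temperature_K: float = TEMPERATURE_K,
) -> float:
    """Odijk-Skolnick-Fixman electrostatic persistence length l_OSF (nm).

    l_OSF = l_B nu^2 / (4 kappa^2) for linear charge density nu (e/nm) and
    Debye screening constant kappa (1/nm).  This is the closed-form estimate
    of how much intramolecular Coulomb repulsion stiffens a semiflexible
    polyelectrolyte; it is used as an independent cross-check of the measured
    stiffening of the charged bead-spring chain.
    """
    if kappa_per_nm <= 0:
        raise ValueError("kappa must be positive")
    lb = bjerrum_length_nm(eps_r, temperature_K)
    return lb * charge_density_e_per_nm**2 / (4.0 * kappa_per_nm**2)
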