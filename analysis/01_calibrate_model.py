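"""Calibrate the coarse-grained model's underdetermined constants.

Computes the harmonic bending constant that gives the bare DNA persistence
length, the physical electrostatic scales (Bjerrum length, Manning effective
charge density, OSF stiffening), and the reference box concentration, and
writes them to results/calibration.json.
"""
import json
from pathlib import Path

from telocompact.builder import bend_mean_cos, calibrate_bending, concentration_uM
from telocompact.electrostatics import (
    bjerrum_length_nm,
    manning_effective_charge_density,
    osf_persistence_length_nm,
)

k_bend = calibrate_bending(target_lp=46.1)
out = {
    "k_bend_kBT": k_bend,
    "mean_cos_at_k_bend": bend_mean_cos(k_bend),
    "bjerrum_length_nm": bjerrum_length_nm(),
    "manning_effective_charge_e_per_nm": manning_effective_charge_density(),
    "osf_stiffening_nm": osf_persistence_length_nm(1.4, 1.0 / 3.0),
    "box_concentration_uM_200_in_500nm": concentration_uM(200, 500.0),
}
Path("results").mkdir(exist_ok=True)
Path("results/calibration.json").write_text(json.dumps(out, indent=2))
print("Bending constant for lp = 46.1 nm:", round(k_bend, 3), "kBT")
print("Manning effective density:", round(out["manning_effective_charge_e_per_nm"], 3), "e/nm")
print("OSF electrostatic stiffening:", round(out["osf_stiffening_nm"], 2), "nm")
print("200 proteins in a 500-nm box:", round(out["box_concentration_uM_200_in_500nm"], 2), "uM")
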