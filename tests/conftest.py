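"""Shared fixtures.

The expensive simulation campaigns (persistence-length measurements, the
4-condition x 5-seed compaction sensitivity verification) run once per
session and are shared between the acceptance tests that need them.
"""

from __future__ import annotations

import numpy as np
import pytest

from telocompact.forcefield import ForceField
from telocompact.protocols import (
    SCALED_COMPACTION_THRESHOLD_NM,
    compaction_run,
    measure_persistence_length,
)

SENSITIVITY_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def lp_uncharged():
    """Persistence length of the uncharged chain (shared t2 measurement)."""
    return measure_persistence_length(
        ForceField().without_electrostatics(), seed=1, n_configs=144
    )


@pytest.fixture(scope="session")
def lp_charged():
    """Persistence length with screened electrostatics (shared t3)."""
    return measure_persistence_length(ForceField(), seed=1, n_configs=144)


@pytest.fixture(scope="session")
def full_strength_runs():
    """Scaled-down compaction runs at full interaction strength, fixed seeds."""
    ff = ForceField()
    return {seed: compaction_run(ff, seed) for seed in SENSITIVITY_SEEDS}


@pytest.fixture(scope="session")
def knockdown_verdicts():
    """Final compacted lengths for each 50%-knockdown arm over the seeds."""
    base = ForceField()
    arms = {
        "specific": base.scaled(specific=0.5),
        "dimerization": base.scaled(dimer=0.5),
        "basic_electrostatics": base.scaled(basic_electrostatics=0.5),
    }
    out = {}
    for name, ff in arms.items():
        finals = []
        for seed in SENSITIVITY_SEEDS:
            res = compaction_run(ff, seed)
            finals.append(res.final_compacted_nm)
        out[name] = finals
    return out


@pytest.fixture(scope="session")
def compaction_threshold():
    return SCALED_COMPACTION_THRESHOLD_NM
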