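import numpy as np
import pytest
from hypothesis import settings

from apscreen.agglaws import TransferRecord
from apscreen.seqspace import Peptide

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# Published reference rows for five strong-gain peptide groups: pentapeptide
# pair, their simulated AP values, normalized hydrophilicities, and the AP of
# the concatenated decapeptide and equimolar mixture.
TABLE1 = [
    # pen1, pen2, ap_pen1, ap_pen2, ap_avepen, logp1', logp2', ap_deca, ap_mix
    ("NRMMR", "DMGID", 1.150, 1.144, 1.147, 0.474, 0.597, 1.659, 1.612),
    ("DMTAL", "IAGAK", 1.155, 1.031, 1.093, 0.451, 0.498, 1.542, 1.366),
    ("RLNCK", "ADMGE", 1.167, 1.125, 1.146, 0.511, 0.653, 1.591, 1.606),
    ("LRLRL", "IQDEC", 1.480, 1.103, 1.292, 0.360, 0.606, 1.731, 1.735),
    ("IVNRR", "EEEQS", 1.174, 1.035, 1.105, 0.466, 0.788, 1.531, 1.490),
]


@pytest.fixture(scope="session")
def table1_records() -> list[TransferRecord]:
    return [
        TransferRecord(
            pen1=Peptide(p1),
            pen2=Peptide(p2),
            ap_pen1=ap1,
            ap_pen2=ap2,
            ap_deca=deca,
            ap_mixpen=mix,
        )
        for p1, p2, ap1, ap2, _ave, _l1, _l2, deca, mix in TABLE1
    ]


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
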