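"""Shared fixtures: the published 22-row reference sweep and cohorts."""

import numpy as np
import pytest

import carpalcone as cc

# Published reference sweep (hook angle 98-140 deg, step 2):
# alpha_deg -> (alpha_rad, cos_alpha, r1_mm, volume_mm3), with
# r2 = 9.8369 mm, L = 19.4 mm, pi = 3.14 in the volume formula.
REFERENCE_SWEEP = {
    98: (1.710422667, -0.139173101, 8.29047701, 5016.416),
    100: (1.745329252, -0.173648178, 8.41499036, 5083.523),
    102: (1.780235837, -0.207911691, 8.53694043, 5149.859),
    104: (1.815142422, -0.241921896, 8.65629006, 5215.364),
    106: (1.850049007, -0.275637356, 8.7730029, 5279.982),
    108: (1.884955592, -0.309016994, 8.8870434, 5343.655),
    110: (1.919862177, -0.342020143, 8.99837682, 5406.326),
    112: (1.954768762, -0.374606593, 9.10696924, 5467.939),
    114: (1.989675347, -0.406736643, 9.2127876, 5528.438),
    116: (2.024581932, -0.438371147, 9.31579965, 5587.77),
    118: (2.059488517, -0.469471563, 9.41597402, 5645.881),
    120: (2.094395102, -0.5, 9.51328019, 5702.718),
    122: (2.129301687, -0.529919264, 9.60768853, 5758.23),
    124: (2.164208272, -0.559192903, 9.69917027, 5812.367),
    126: (2.199114858, -0.587785252, 9.78769754, 5865.078),
    128: (2.234021443, -0.615661475, 9.87324339, 5916.317),
    130: (2.268928028, -0.64278761, 9.95578176, 5966.036),
    132: (2.303834613, -0.669130606, 10.0352875, 6014.19),
    134: (2.338741198, -0.69465837, 10.1117364, 6060.735),
    136: (2.373647783, -0.7193398, 10.1851051, 6105.628),
    138: (2.408554368, -0.743144825, 10.2553714, 6148.827),
    140: (2.443460953, -0.766044443, 10.3225138, 6190.293),
}

R2_MM = 9.8369
L_MM = 19.4
PI_VOLUME = 3.14


@pytest.fixture(scope="session")
def reference_calibration():
    return cc.default_calibration()


@pytest.fixture(scope="session")
def reference_table():
    return cc.default_volume_table()


@pytest.fixture()
def default_cohort():
    return cc.generate_cohort(cc.CohortConfig(seed=7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
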