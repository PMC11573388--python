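import numpy as np
import pytest

import stsmap as sm
from stsmap import com as cm


@pytest.fixture(scope="session")
def small_cohort():
    """Small zero-noise cohort shared across tests (3 + 2 subjects, 3 cycles)."""
    cfg = sm.CohortConfig(n3=3, n4=2, n_cycles=3, noise_sd=0.0)
    return sm.generate_cohort(cfg, seed=5)


def cohort_xy(cohort, subject_id):
    """Sagittal CoM coordinates of one cohort subject, via the com module."""
    markers = cohort.marker_trials[subject_id]
    com3d = cm.estimate_com(markers)
    return cm.to_sagittal_relative(
        com3d,
        cm.marker_xyz(markers, "malleolus_left"),
        cm.marker_xyz(markers, "malleolus_right"),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
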