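import numpy as np
import pytest

from metsperf.geometry import AcquisitionGeometry
from metsperf.phantom import build_anatomy, week5_preset


@pytest.fixture(scope="session")
def geometry():
    return AcquisitionGeometry()


@pytest.fixture(scope="session")
def small_geometry():
    """Reduced grid for fast per-voxel tests."""
    return AcquisitionGeometry(matrix=64, dsc_matrix=32, n_slices=6,
                               n_dsc_slices=2, n_frames=120)


@pytest.fixture(scope="session")
def anatomy(geometry):
    return build_anatomy(geometry)


@pytest.fixture(scope="session")
def preset():
    return week5_preset()


@pytest.fixture(scope="session")
def noiseless_preset():
    """Zero image/DSC noise, no recirculation or drift - for exact oracles."""
    return week5_preset(anat_noise_sd=0.0, dsc_noise_sd=0.0,
                        recirculation_fraction=0.0, dsc_drift_per_s=0.0)


@pytest.fixture(scope="session")
def week5_run():
    """One fully analyzed week-5 cohort, shared across tests."""
    from metsperf.pipeline import run_week5_cohort

    return run_week5_cohort(seed=11)
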