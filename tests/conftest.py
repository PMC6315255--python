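import numpy as np
import pandas as pd
import pytest

from funcprofile.pipeline import build_cohort_data
from funcprofile.segmentation import SegmentationConfig
from funcprofile.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully structured cohort (20 subjects, 2 days)."""
    return simulate_cohort(SimulationConfig(n_subjects=20, n_days=2, seed=42))


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    """Segmented features for the small cohort."""
    return build_cohort_data(
        small_sim.epochs,
        small_sim.covariates,
        small_sim.capacity,
        SegmentationConfig(seed=7),
    )
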