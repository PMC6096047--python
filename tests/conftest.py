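import logging

import numpy as np
import pytest

from mvblife.cohort import CohortSpec, NoiseSpec, generate_cohort

logging.getLogger("mvblife").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject dedifferentiation cohort at reduced voxel count."""
    spec = CohortSpec(n_subjects=6, scenario="dedifferentiation",
                      n_voxels_per_roi=40, rng_seed=123)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def noiseless_subject():
    """One subject with zero noise: the GLM must recover betas exactly."""
    spec = CohortSpec(n_subjects=1, scenario="null", n_voxels_per_roi=20,
                      noise=NoiseSpec(ar1_rho=0.0, sigma=0.0, sigma_shared=0.0),
                      rng_seed=7)
    return generate_cohort(spec)[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
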