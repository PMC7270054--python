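import logging

import numpy as np
import pytest

from connectopy.connectopic_mapping import fit_connectopic_map
from connectopy.synthetic_cohort import (
    CohortSpec,
    make_seed_mesh,
    make_target_space,
    plant_gradients,
    simulate_cohort,
)

logging.getLogger("connectopy").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def mesh20():
    return make_seed_mesh(20, 20)


@pytest.fixture(scope="session")
def noiseless_m1_cohort(mesh20):
    """Three noiseless subjects, one session, planted 1-D gradient."""
    truth = plant_gradients(mesh20, 1, 0)
    spec = CohortSpec(
        n_subjects=3, n_sessions=1, sigma_subject=0.0, sigma_session=0.0, rng_seed=0
    )
    matrices, target_space = simulate_cohort(truth, spec, 120)
    return truth, spec, matrices, target_space


@pytest.fixture(scope="session")
def noiseless_m2_cohort(mesh20):
    """Eight noiseless subjects, one session, two planted gradients."""
    truth = plant_gradients(mesh20, 2, 0)
    spec = CohortSpec(
        n_subjects=8, n_sessions=1, sigma_subject=0.0, sigma_session=0.0, rng_seed=0
    )
    matrices, target_space = simulate_cohort(truth, spec, 120)
    return truth, spec, matrices, target_space


@pytest.fixture(scope="session")
def m2_maps(noiseless_m2_cohort):
    """Fitted two-mode maps for the noiseless m=2 cohort."""
    truth, spec, matrices, _ = noiseless_m2_cohort
    return {
        key: fit_connectopic_map(cm, 2, subject_id=key[0], session_id=key[1])[0]
        for key, cm in matrices.items()
    }


@pytest.fixture(scope="session")
def small_mesh():
    return make_seed_mesh(8, 8)
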