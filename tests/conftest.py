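import os

# single-threaded BLAS: avoids thread-pool oversubscription on small
# machines and keeps floating-point reduction order (hence seeded training
# trajectories) reproducible
for var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(var, "1")

import numpy as np
import pytest

from neurossl.cohort import CohortConfig, generate_cohort, generate_volumes


@pytest.fixture(scope="session")
def tiny_config():
    return CohortConfig(n_subjects=14, n_sites=2, visits_range=(1, 2),
                        grid_size=16, pet_missing_prob=0.3, seed=42)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    table, subjects = generate_cohort(tiny_config)
    volumes = generate_volumes(subjects, tiny_config)
    return table, subjects, volumes


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
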