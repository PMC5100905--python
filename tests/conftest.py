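import numpy as np
import pytest

from wmhtracts import simulate_cohort
from wmhtracts.atlas import merge_bilateral, threshold_atlas
from wmhtracts.simulate import generate_atlas, generate_lesions, generate_covariates

MASTER_SEED = 7


@pytest.fixture(scope="session")
def small_atlas():
    """A reduced-grid atlas, cheap enough for per-test thresholding."""
    return generate_atlas(shape=(24, 28, 24), seed=MASTER_SEED)


@pytest.fixture(scope="session")
def small_rois(small_atlas):
    return merge_bilateral(threshold_atlas(small_atlas, 10))


@pytest.fixture(scope="session")
def small_maps():
    return generate_lesions(n_subjects=25, shape=(24, 28, 24), seed=MASTER_SEED,
                            median_volume_ml=4.0)


@pytest.fixture(scope="session")
def cohort_run():
    """One full default-sized synthetic cohort shared across tests."""
    maps, atlas, rois, cohort, truth = simulate_cohort(seed=MASTER_SEED)
    return {"maps": maps, "atlas": atlas, "rois": rois, "cohort": cohort, "truth": truth}


@pytest.fixture(scope="session")
def covariates167():
    return generate_covariates(n_subjects=167, seed=MASTER_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(MASTER_SEED)
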