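import warnings

import numpy as np
import pytest

from tumorcbir import (
    PhantomParams,
    PipelineConfig,
    encode_folds,
    generate_cohort,
)

# sklearn's EM emits ConvergenceWarning when the 200-iteration cap is hit on
# small noisy samples; the fitted vocabulary is still usable.
warnings.filterwarnings("ignore", message=".*did not converge.*")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """12-patient phantom cohort, small images: fast end-to-end fixture."""
    params = PhantomParams(
        n_patients=12,
        slices_per_patient=(2, 2),
        image_size=48,
        tumor_radius_range=(5.0, 8.0),
        seed=3,
    )
    return generate_cohort(params)


@pytest.fixture(scope="session")
def small_config():
    return PipelineConfig.ci_profile(R=4, K=4, N=2, pca_sample_size=5000,
                                     gmm_sample_size=4000, seed=3)


@pytest.fixture(scope="session")
def ci_cohort():
    """The study-condition phantom cohort: 48 patients, 3 classes, separable."""
    return generate_cohort(PhantomParams(seed=1))


@pytest.fixture(scope="session")
def ci_config():
    return PipelineConfig.ci_profile(seed=1)


@pytest.fixture(scope="session")
def ci_encodings(ci_cohort, ci_config):
    """Per-fold signatures of the study cohort (models fit per training fold).

    Session-scoped because encoding dominates the cost of every retrieval
    check; labels are not consumed here, so permutation experiments can
    re-score these encodings.
    """
    return encode_folds(ci_cohort, ci_config, n_folds=5)
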