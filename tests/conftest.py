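import numpy as np
import pytest

from desilipid import SyntheticConfig, generate_cohort
from desilipid.pipeline import build_patient_matrix

PLANTED_MZ = (688.4921, 699.5014, 714.5123, 740.5229, 864.5707, 913.5778, 915.5901)


@pytest.fixture(scope="session")
def small_cfg():
    """A desk-scale cohort: 8 cancer / 6 benign patients, 10x10 images."""
    return SyntheticConfig(
        n_cancer=8, n_benign=6, image_shape=(10, 10), n_background_peaks=30,
        n_proteins=40, n_differential_proteins=12, seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return generate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    imgs, masks, _metas = small_cohort
    return build_patient_matrix(imgs, masks)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
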