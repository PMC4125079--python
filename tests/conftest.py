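import numpy as np
import pytest

from polyadapt.calibration import fit_model_from_dataset
from polyadapt.fixtures import FixtureSpec, make_dataset


@pytest.fixture(scope="session")
def small_spec():
    return FixtureSpec(M=8, L_gwas=25, K_pool=3000, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return make_dataset(small_spec)


@pytest.fixture(scope="session")
def small_model(small_dataset):
    return fit_model_from_dataset(small_dataset, n_cov_snps=2000, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
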