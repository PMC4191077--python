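import numpy as np
import pytest

from hemopk import ExtinctionTable, StudyConfig


@pytest.fixture(scope="session")
def table():
    return ExtinctionTable.default()


@pytest.fixture(scope="session")
def one_compartment_config():
    """No-binding arm: unbound Hb eliminated first-order, noise-free."""
    return StudyConfig(hp_dose_g=0.0, basal_hp_uM=0.0, k_el_free=0.2,
                       noise_cv=0.0, loq_uM=0.0, n_subjects=1, seed=7)


@pytest.fixture(scope="session")
def prednisone_config():
    """Two-analyte arm with a high endogenous Hp pool (reference settings)."""
    return StudyConfig(basal_hp_uM=360.0, n_subjects=6, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
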