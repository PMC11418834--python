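import numpy as np
import pytest

from maat import VonMisesModel, reference_equation_set


@pytest.fixture(scope="session")
def ref_equations():
    """One shape-conforming synthetic equation per coupling kind."""
    return reference_equation_set(seed=0)


@pytest.fixture(scope="session")
def ref_by_kind(ref_equations):
    return {eq.coupling_id: eq for eq in ref_equations}


@pytest.fixture(scope="session")
def truth_model():
    return VonMisesModel(37.0, 15.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
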