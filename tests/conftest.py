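import numpy as np
import pytest

from switchscan.synthetic_data import GNMSpec, gnm_ensemble


@pytest.fixture(scope="session")
def gnm20():
    """20-residue elastic-network ensemble with its analytic covariance."""
    return gnm_ensemble(GNMSpec(n_residues=20, contact_cutoff=10.0,
                                n_frames=6000, seed=11,
                                backbone_geometry="helix"))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")
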