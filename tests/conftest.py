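import numpy as np
import pytest

from morphabc import ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def model2_params():
    """Model-2 study conditions at reduced horizon (desk scale)."""
    return ModelParams(model_id=2, n_steps=200)


@pytest.fixture
def model1_params():
    """A controlled Model-1 operating point (sub-explosive bifurcation)."""
    return ModelParams(
        model_id=1, p_bra=0.008, R=2.5e-3, v=100.0, n_steps=300
    )
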