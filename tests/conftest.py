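import numpy as np
import pytest

from ringfba.model_core import apply_medium, yes_medium
from ringfba.synthetic_models import (
    all_defects,
    make_core_model,
    make_phenotype_library,
    plant_defects,
)


@pytest.fixture
def core_model():
    return make_core_model()


@pytest.fixture
def yes_model(core_model):
    return apply_medium(core_model, yes_medium(core_model))


@pytest.fixture
def defected():
    """Core model with every defect class planted, plus its matched library."""
    model, truth = plant_defects(make_core_model(), all_defects())
    records = make_phenotype_library(model, truth)
    return model, truth, records


@pytest.fixture
def rng():
    return np.random.default_rng(20120705)
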