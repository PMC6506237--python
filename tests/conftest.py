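import numpy as np
import pytest

from editscope import (
    EditingProfile,
    QualityModel,
    SimConfig,
    make_amplicon_reference,
    make_gene_models,
)
from editscope.models import ERROR_FREE


@pytest.fixture(scope="session")
def spec():
    """A 240-nt amplicon with a target A at protospacer position 5."""
    return make_amplicon_reference(seed=11, length=240,
                                   target_a_protospacer_position=5,
                                   name="test_amp")


@pytest.fixture(scope="session")
def models():
    """A small mini-genome: 12 transcripts on 2 chromosomes."""
    return make_gene_models(seed=5, n_transcripts=12)


@pytest.fixture
def q30():
    return QualityModel(mean_q=30, sd_q=0)


@pytest.fixture
def error_free():
    return ERROR_FREE


@pytest.fixture
def flat_profile(spec):
    """Every adenosine at rate 0.02."""
    return EditingProfile.from_pairs(
        ((int(p), 0.02) for p in spec.adenosine_positions))
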