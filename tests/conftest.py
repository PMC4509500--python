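"""Shared fixtures: one phantom cohort, shape model and segmented study.

The expensive objects (75-geometry training set, trained model, one
segmented nominal study) are built once per session and reused across
test modules; all randomness is seeded.
"""

import numpy as np
import pytest

from aaaseg.config import PipelineConfig
from aaaseg.phantom import PhantomSpec, generate_study, sample_training_shapes
from aaaseg.segmentation import segment_study
from aaaseg.shape_model import build_shape_model

TRAINING_SEED = 123
STUDY_SEED = 42


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def training_shapes(phantom_spec):
    return sample_training_shapes(75, phantom_spec, seed=TRAINING_SEED)


@pytest.fixture(scope="session")
def shape_model(training_shapes):
    return build_shape_model(training_shapes)


@pytest.fixture(scope="session")
def nominal_study(phantom_spec):
    return generate_study(phantom_spec, STUDY_SEED)


@pytest.fixture(scope="session")
def nominal_result(nominal_study, shape_model):
    return segment_study(
        nominal_study.pair, nominal_study.seed_point, shape_model, PipelineConfig()
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
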