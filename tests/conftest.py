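"""Shared fixtures: one default atlas per session plus small cohorts."""

import numpy as np
import pytest
from hypothesis import settings

import lesionmap as lm
from lesionmap.calibration import DISCOVERY_LIKE
from lesionmap.synthetic import generate_cohort_arrays

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def atlas():
    return lm.make_atlas((48, 56, 48), seed=1)


@pytest.fixture(scope="session")
def small_atlas():
    return lm.make_atlas((32, 32, 32), seed=1)


@pytest.fixture(scope="session")
def discovery_cohort(atlas):
    """In-memory discovery-style cohort: table, masks, atlas."""
    table, masks, _ = generate_cohort_arrays(DISCOVERY_LIKE, seed=7, atlas=atlas)
    return table, masks, atlas


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
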