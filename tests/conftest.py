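import logging

import numpy as np
import pandas as pd
import pytest

from picniccval.model import default_model_spec
from picniccval.simulate import SyntheticConfig, generate_cohorts

logging.getLogger("picniccval").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def spec():
    return default_model_spec()


def make_episode(**overrides) -> pd.DataFrame:
    """One fully specified episode row, fields overridable."""
    base = {
        "study_id": "s1",
        "patient_id": "p1",
        "tumour_type": "Acute lymphoblastic leukaemia / other",
        "temperature": 38.5,
        "severely_unwell": 0,
        "haemoglobin": 9.5,
        "wcc": 1.2,
        "amc": 0.1,
        "mdi": 0,
    }
    base.update(overrides)
    return pd.DataFrame([base])


@pytest.fixture(scope="session")
def small_cohorts(spec):
    """Seven small synthetic studies (quarter scale) for fast pipeline tests."""
    cfg = SyntheticConfig(seed=42).scaled(0.25)
    return generate_cohorts(cfg, spec)


@pytest.fixture(scope="session")
def correct_spec_cohort(spec):
    """A single large cohort with outcomes drawn from the model's own risks."""
    cfg = SyntheticConfig(
        study_sizes=(20000,), target_mdi=None, intercept_shift=0.0, slope=1.0,
        seed=99,
    )
    return generate_cohorts(cfg, spec)["study1"]


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
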