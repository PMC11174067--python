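import numpy as np
import pytest

from fibertol.datamodel import DOSE_BY_SEX, SymptomDiary
from fibertol.simulate import CohortConfig, generate_cohort


def make_diary(
    subject_id="S1",
    arm="AX",
    sex="F",
    overall=None,
    flatulence=None,
    bloating=None,
    stomachache=None,
):
    """Build a valid diary, defaulting every trajectory to all-zero."""
    zero = [0] * 7
    ratings = {
        "overall": list(overall or zero),
        "flatulence": list(flatulence or zero),
        "bloating": list(bloating or zero),
        "stomachache": list(stomachache or zero),
    }
    return SymptomDiary(
        subject_id=subject_id,
        arm=arm,
        sex=sex,
        dose_g_per_day=DOSE_BY_SEX[sex],
        ratings=ratings,
    )


@pytest.fixture
def diary_factory():
    return make_diary


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic cohort, shared across tests."""
    return generate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240611)
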