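import numpy as np
import pytest

from burneval.study_data import Rating, RegionCase, StudyTables


def make_case(cid="C1", pid="P1", age=30.0, sex="male", region="torso", quality=9):
    return RegionCase(cid, pid, age, sex, region, quality)


def make_rating(cid="C1", rater="model_01", kind="model", tbsa=5.0, depth=1):
    return Rating(cid, rater, kind, tbsa, depth)


@pytest.fixture
def small_study():
    """Two region-cases on two patients, fully rated by one model rater,
    two physicians and three panelists."""
    cases = [
        make_case("C1", "P1", age=5.0, region="upper_extremity"),
        make_case("C2", "P2", age=40.0, region="lower_extremity"),
    ]
    ratings = []
    for cid, base in (("C1", 4.0), ("C2", 8.0)):
        ratings.append(make_rating(cid, "model_01", "model", base + 1.0, 1))
        for j, kind_tbsa in enumerate((base + 0.5, base - 0.5)):
            ratings.append(make_rating(cid, f"physician_{j+1:02d}", "physician", kind_tbsa, 1))
        for j, t in enumerate((base, base + 0.5, base - 0.5)):
            ratings.append(make_rating(cid, f"panelist_{j+1:02d}", "panelist", t, 1))
    return StudyTables(cases=cases, ratings=ratings)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
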