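import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def study65():
    """One shared small synthetic study (65 items, 17 features)."""
    from actionrsa import GroundTruth, make_study

    return make_study(GroundTruth.experiment2(), seed=7)


@pytest.fixture(scope="session")
def group_map():
    return {
        "environment": "visual", "fc8": "visual",
        "category": "action", "effectors": "action",
        "transitivity": "action", "activity": "action",
        "n_agents": "social-affective", "sociality": "social-affective",
        "valence": "social-affective", "arousal": "social-affective",
    }


@pytest.fixture
def small_rating_table():
    """Three raters x 6 items x 1 feature, one repetitive rater."""
    rows = []
    vals = {
        "good1": [1, 2, 3, 4, 5, 3],
        "good2": [2, 2, 3, 5, 4, 3],
        "flat": [3, 4, 3, 4, 3, 4],  # only two unique values
    }
    for rater, v in vals.items():
        rows += [(rater, i, "sociality", x) for i, x in enumerate(v)]
    from actionrsa import RatingTable

    return RatingTable(
        pd.DataFrame(rows, columns=["rater", "item", "feature", "rating"]),
        pd.Series({"good1": True, "good2": True, "flat": True}),
    )


def subset_rdm(rdm, items):
    """Restrict an RDM to an item subset (test helper)."""
    import scipy.spatial.distance as ssd

    from actionrsa import RDM

    sq = rdm.square()[np.ix_(items, items)]
    return RDM(ssd.squareform(sq, checks=False), len(items))
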