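import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mcdakit.criteria import default_criteria_set
from mcdakit.panel import PanelAppraisal
from mcdakit.synthetic import default_panel_spec, fixture_published_panel, sample_panel

settings.register_profile(
    "default", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def criteria_set():
    return default_criteria_set()


@pytest.fixture(scope="session")
def fixture_panel():
    return fixture_published_panel()


@pytest.fixture(scope="session")
def sampled_panel():
    return sample_panel(default_panel_spec(seed=0))


def make_panel(weights, scores, criteria=None) -> PanelAppraisal:
    """Small helper: build a panel from integer row-lists."""
    weights = np.atleast_2d(weights)
    criteria = criteria or [f"c{i + 1}" for i in range(weights.shape[1])]
    members = [f"m{i + 1}" for i in range(weights.shape[0])]
    return PanelAppraisal(
        weights=pd.DataFrame(weights, index=members, columns=criteria),
        scores=pd.DataFrame(np.atleast_2d(scores), index=members, columns=criteria),
    )
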