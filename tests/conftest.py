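import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_fixtures():
    from dinadif.engine import StudyFixtures

    return StudyFixtures.packaged()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_design():
    """A small 6-item / 2-attribute design for fast estimation tests."""
    from dinadif.dina import ItemParameterSet, QMatrix

    q = QMatrix(
        np.array(
            [
                [1, 0],
                [0, 1],
                [1, 0],
                [0, 1],
                [1, 1],
                [1, 1],
            ]
        )
    )
    params = ItemParameterSet(
        np.array([0.15, 0.25, 0.10, 0.20, 0.30, 0.12]),
        np.array([0.20, 0.10, 0.25, 0.15, 0.10, 0.22]),
    )
    return q, params
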