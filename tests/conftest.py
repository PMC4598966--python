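import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from careshed import Frame, PointSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_points(xy, prefix="p", frame=Frame.PLANAR, zone_ids=None):
    xy = np.asarray(xy, dtype=float)
    ids = np.array([f"{prefix}{i}" for i in range(len(xy))], dtype=object)
    return PointSet(ids=ids, xy=xy, frame=frame, zone_ids=zone_ids)


@pytest.fixture
def small_participants():
    return make_points([[0, 0], [100, 0], [0, 250], [700, 700]], prefix="p")


@pytest.fixture
def small_providers():
    return make_points([[0, 0], [500, 0], [0, 1000]], prefix="s")
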