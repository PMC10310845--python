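import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stillwatch.landmarks import N_LANDMARKS, LandmarkFrame, LandmarkSeries

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def build_frame(
    t: float,
    nose_xy=(100.0, 100.0),
    left_eye_xy=(80.0, 60.0),
    right_eye_xy=(143.0, 60.0),
    expressions=None,
) -> LandmarkFrame:
    """A frame with controlled eye centres and nose tip.

    All six markers of each eye sit at the eye's centre, so the centre mean
    is exact; every other landmark sits at the origin.
    """
    pts = np.zeros((N_LANDMARKS, 2))
    pts[36:42] = left_eye_xy
    pts[42:48] = right_eye_xy
    pts[30] = nose_xy
    return LandmarkFrame(timestamp=t, points=pts, expressions=expressions)


def nose_walk_series(
    steps_px,
    iod_px: float = 63.0,
    participant_id: str = "P001",
    condition: str = "control",
) -> LandmarkSeries:
    """1 Hz series whose nose moves ``steps_px[k]`` pixels (along x) between
    seconds k−1 and k; eye centres are fixed with the given pixel IOD."""
    x = 100.0
    frames = []
    for k, step in enumerate([0.0, *steps_px]):
        x += step
        frames.append(
            build_frame(float(k), nose_xy=(x, 100.0),
                        left_eye_xy=(0.0, 0.0), right_eye_xy=(iod_px, 0.0))
        )
    return LandmarkSeries(participant_id, condition, frames)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
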