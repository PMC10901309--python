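import numpy as np
import pytest

from mtmkin.landmark_io import LandmarkFrame, LandmarkSeries
from mtmkin.synthetic import SyntheticConfig, simulate, template_pose


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def template_frame():
    return LandmarkFrame(frame_index=0, points=template_pose())


def make_noisy_frame(rng, orientation=0.0, noise=0.01, scale=0.25):
    """An infant-plausible random frame: template pose + per-landmark noise."""
    pts = template_pose(scale=scale, orientation=orientation)
    return LandmarkFrame(
        frame_index=0, points=pts + rng.normal(scale=noise, size=pts.shape)
    )


@pytest.fixture
def noisy_frame_factory(rng):
    def factory(orientation=0.0, noise=0.01):
        return make_noisy_frame(rng, orientation=orientation, noise=noise)

    return factory


@pytest.fixture
def short_series():
    """A quiet 5-second synthetic series for I/O and summary tests."""
    cfg = SyntheticConfig(duration_s=5.0, fps=30.0, seed=7, video_id="short")
    return simulate(cfg).series


@pytest.fixture
def tiny_series():
    """Two identical valid frames."""
    pts = template_pose()
    coords = np.stack([pts, pts])
    return LandmarkSeries(video_id="tiny", fps=30.0, coords=coords)
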