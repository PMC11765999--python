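import numpy as np
import pytest

from blinkdetect import EyeSequence, SegmentationConfig
from blinkdetect.synthetic import (
    BlinkSchedule,
    SceneConfig,
    ScheduledBlink,
    render_sequence,
)


class VoteReplayClassifier:
    """Replays a fixed per-window vote sequence (position-indexed),
    mimicking how a deterministic classifier scores the dense-overlap
    window stream."""

    def __init__(self, votes):
        self.votes = np.asarray(votes, dtype=float)
        self._next = 0

    def reset(self):
        self._next = 0

    def __call__(self, windows):
        windows = np.asarray(windows)
        k = 1 if windows.ndim == 3 else windows.shape[0]
        out = self.votes[self._next : self._next + k]
        self._next += k
        return float(out[0]) if windows.ndim == 3 else out


def constant_classifier(value):
    def clf(windows):
        windows = np.asarray(windows)
        if windows.ndim == 3:
            return value
        return np.full(windows.shape[0], value)

    return clf


def gray_sequence(n_frames, level=128):
    """A flat mid-gray sequence; pixel content is irrelevant for
    position-indexed classifiers."""
    frames = np.full((n_frames, 48, 48), level, dtype=np.uint8)
    return EyeSequence(frames=frames)


@pytest.fixture
def default_cfg():
    return SegmentationConfig()


@pytest.fixture
def well_separated_schedule():
    """10 blinks with gaps far exceeding one window length."""
    blinks = []
    start = 60
    for duration, core in zip(
        [12, 10, 14, 12, 11, 13, 12, 9, 15, 12],
        [3, 4, 3, 4, 3, 3, 4, 3, 4, 3],
    ):
        blinks.append(ScheduledBlink(start=start, duration=duration, core=core))
        start += duration + 60
    return BlinkSchedule(blinks=blinks, n_frames=start + 60)


@pytest.fixture
def rendered_fixture(well_separated_schedule):
    seq, truth = render_sequence(
        well_separated_schedule, SceneConfig(rng_seed=7)
    )
    return seq, truth, well_separated_schedule
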