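"""Core domain types shared across the blink-detection pipeline.

Conventions
-----------
* Frame indices are **1-based** and intervals are **inclusive** on both
  ends, matching the annotation style of clinical blink ground truth.
* Frame stacks are stored as numpy arrays of shape ``(N, H, W)`` with
  ``H = W = 48`` and 8-bit intensities; the temporal axis comes first
  (the natural axis order for multi-page image stacks).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

#: Spatial side length of a cropped eye region, in pixels.
EYE_SIZE = 48

#: Default subsequence (window) length in frames, ~300 ms at 25 fps.
DEFAULT_NS = 12


class Eye(str, enum.Enum):
    """Which eye a sequence or annotation refers to."""

    LEFT = "left"
    RIGHT = "right"


@dataclass
class EyeSequence:
    """A cropped single-eye grayscale video: ``frames`` has shape (N, 48, 48).

    Frames are 8-bit (values 0-255). Frame ``i`` (1-based) lives at
    ``frames[i - 1]``.
    """

    frames: np.ndarray
    side: Eye = Eye.LEFT
    fps: float = 25.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (N, H, W) stack, got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("sequence must contain at least one frame")
        if self.frames.min() < 0 or self.frames.max() > 255:
            raise ValueError("frame intensities must lie in [0, 255]")
        self.side = Eye(self.side)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True, order=True)
class BlinkInterval:
    """One blink as an inclusive 1-based [start, end] frame interval."""

    start: int
    end: int
    side: Eye = Eye.LEFT

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) must be >= start ({self.start})")

    @property
    def duration(self) -> int:
        """Blink length in frames (inclusive counting)."""
        return self.end - self.start + 1


@dataclass
class SegmentationConfig:
    """Parameters of the accumulator-to-intervals segmentation stage.

    Parameters
    ----------
    ns : subsequence length fed to the classifier (frames).
    se_length : flat structuring-element length for grayscale closing;
        must be odd.
    threshold_T : accumulator cutoff deciding which watershed segments
        are blinks; the natural choice is about half the expected blink
        duration, i.e. ``ns // 2``.
    binarize_cutoff : probability cutoff turning a classifier score into
        a 0/1 vote before accumulation.
    soft_votes : accumulate raw probabilities instead of binary votes
        (non-default extension; the canonical accumulator is integer).
    """

    ns: int = DEFAULT_NS
    se_length: int = 3
    threshold_T: float = 6
    binarize_cutoff: float = 0.5
    soft_votes: bool = False

    def __post_init__(self) -> None:
        if self.ns < 1:
            raise ValueError("ns must be >= 1")
        if self.se_length < 1 or self.se_length % 2 == 0:
            raise ValueError(f"se_length must be odd and >= 1, got {self.se_length}")
        if not (0 < self.threshold_T <= self.ns):
            raise ValueError(
                f"threshold_T must lie in (0, ns={self.ns}], got {self.threshold_T}"
            )
        if not (0 < self.binarize_cutoff < 1):
            raise ValueError("binarize_cutoff must lie in (0, 1)")


@dataclass
class Accumulator:
    """Per-frame vote signal built from overlapping window predictions.

    ``values[i - 1]`` counts the positive windows covering frame ``i``;
    for binary votes it is integer-valued and bounded by ``ns``.
    """

    values: np.ndarray
    ns: int = DEFAULT_NS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise ValueError("accumulator values must be one-dimensional")
        if len(self.values) and (
            self.values.min() < 0 or self.values.max() > self.ns
        ):
            raise ValueError(f"accumulator values must lie in [0, ns={self.ns}]")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SubsequenceWindow:
    """A contiguous Ns-frame slice of an :class:`EyeSequence`.

    ``start`` is the 1-based index of the first frame; ``data`` has shape
    ``(ns, 48, 48)`` and is a view into the parent stack.
    """

    start: int
    data: np.ndarray = field(repr=False)

    @property
    def length(self) -> int:
        return self.data.shape[0]

    @property
    def end(self) -> int:
        """1-based index of the last frame covered by the window."""
        return self.start + self.length - 1


class SequenceTooShortError(ValueError):
    """Raised when a sequence has fewer frames than one window."""


class ClassifierContractError(ValueError):
    """Raised when a classifier emits a score outside [0, 1]."""
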