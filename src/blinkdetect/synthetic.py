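"""Procedural synthetic eye-video fixtures with blink annotations.

The generator emulates the *temporal* statistics of clinical blink
video -- 48x48 cropped eye regions at 25 fps, blinks with a median
duration of ~12 frames (300 ms) and a 3-4 frame closed core -- so the
accumulator, metrics and training code can be exercised without any
recorded data. The scene itself is deliberately schematic: a bright
sclera ellipse with a dark iris disk on a skin background, occluded by
a skin-colored eyelid that follows a piecewise-linear
close-hold-open aperture profile, plus additive Gaussian pixel noise
and per-frame translational jitter. No visual realism is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.training import LabeledWindowSet
from .types import DEFAULT_NS, EYE_SIZE, BlinkInterval, Eye, EyeSequence

#: Minimum aperture fraction during the closed core (lids never render
#: a mathematically zero gap in real video either).
CORE_APERTURE = 0.06


@dataclass(frozen=True)
class ScheduledBlink:
    """One blink: start frame (1-based), total duration, closed-core length."""

    start: int
    duration: int
    core: int

    def __post_init__(self) -> None:
        if self.duration < 3:
            raise ValueError("blink duration must be >= 3 frames")
        if not 1 <= self.core <= self.duration:
            raise ValueError("core must lie within the blink duration")

    @property
    def end(self) -> int:
        return self.start + self.duration - 1

    @property
    def core_interval(self) -> tuple[int, int]:
        """1-based inclusive frame range of the closed core (centered)."""
        closing = (self.duration - self.core) // 2
        lo = self.start + closing
        return lo, lo + self.core - 1

    def interval(self, side: Eye = Eye.LEFT) -> BlinkInterval:
        return BlinkInterval(start=self.start, end=self.end, side=side)


@dataclass
class BlinkSchedule:
    """Sorted, non-overlapping blinks within an N-frame sequence."""

    blinks: list[ScheduledBlink]
    n_frames: int
    fps: float = 25.0

    def __post_init__(self) -> None:
        self.blinks = sorted(self.blinks, key=lambda b: b.start)
        for b in self.blinks:
            if b.start < 1 or b.end > self.n_frames:
                raise ValueError(f"blink {b} outside sequence of {self.n_frames}")
        for prev, nxt in zip(self.blinks, self.blinks[1:]):
            if nxt.start <= prev.end:
                raise ValueError(f"overlapping blinks: {prev} and {nxt}")

    def intervals(self, side: Eye = Eye.LEFT) -> list[BlinkInterval]:
        return [b.interval(side) for b in self.blinks]


@dataclass
class SceneConfig:
    """Appearance and nuisance parameters of the rendered eye scene."""

    skin_level: int = 150
    sclera_level: int = 230
    iris_level: int = 60
    iris_radius: float = 7.0
    aperture_ry: float = 11.0  # vertical semi-axis of the open fissure, px
    fissure_rx: float = 19.0  # horizontal semi-axis, px
    noise_sd: float = 4.0
    jitter_px: float = 0.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for level in (self.skin_level, self.sclera_level, self.iris_level):
            if not 0 <= level <= 255:
                raise ValueError("intensity levels must lie in [0, 255]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def sample_durations(
    n: int, rng: np.random.Generator, mean: float = 12.0, sd: float = 2.0
) -> np.ndarray:
    """Blink durations in frames: discretized normal, median 12, min 6."""
    return np.maximum(6, np.rint(rng.normal(mean, sd, size=n))).astype(int)


def sample_schedule(
    n_frames: int,
    mean_gap: float = 100.0,
    seed: int = 0,
    fps: float = 25.0,
    duration_mean: float = 12.0,
    duration_sd: float = 2.0,
    margin: int = DEFAULT_NS,
) -> BlinkSchedule:
    """Draw a reproducible blink schedule.

    Blink onsets follow gaps drawn from an exponential distribution with
    mean ``mean_gap`` frames (minimum 1 frame between blinks); durations
    are discretized-normal around 12 frames; closed cores are 3 or 4
    frames with equal probability. ``margin`` keeps blinks away from the
    sequence ends where edge frames receive fewer window votes.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be positive")
    if mean_gap < 2:
        raise ValueError(
            f"mean_gap={mean_gap} too dense; blinks would systematically overlap"
        )
    rng = np.random.default_rng(seed)
    blinks: list[ScheduledBlink] = []
    pos = 1 + margin + int(rng.exponential(mean_gap / 2))
    while True:
        duration = int(sample_durations(1, rng, duration_mean, duration_sd)[0])
        core = int(rng.integers(3, 5))  # 3 or 4 frames, equal probability
        if pos + duration - 1 > n_frames - margin:
            break
        blinks.append(ScheduledBlink(start=pos, duration=duration, core=core))
        pos += duration + max(1, int(rng.exponential(mean_gap)))
    return BlinkSchedule(blinks=blinks, n_frames=n_frames, fps=fps)


def _aperture_profile(schedule: BlinkSchedule) -> np.ndarray:
    """Eyelid openness in [0, 1] per frame: 1 = fully open."""
    aperture = np.ones(schedule.n_frames)
    for b in schedule.blinks:
        core_lo, core_hi = b.core_interval
        closing = core_lo - b.start  # frames spent closing
        opening = b.end - core_hi  # frames spent opening
        for i, frame in enumerate(range(b.start, core_lo)):
            frac = (i + 1) / (closing + 1)
            aperture[frame - 1] = 1.0 - (1.0 - CORE_APERTURE) * frac
        aperture[core_lo - 1 : core_hi] = CORE_APERTURE
        for i, frame in enumerate(range(core_hi + 1, b.end + 1)):
            frac = (i + 1) / (opening + 1)
            aperture[frame - 1] = CORE_APERTURE + (1.0 - CORE_APERTURE) * frac
    return aperture


def _render_frame(
    aperture: float, scene: SceneConfig, dx: float, dy: float
) -> np.ndarray:
    """One 48x48 uint8 frame at the given eyelid openness."""
    size = EYE_SIZE
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cx, cy = size / 2 + dx, size / 2 + dy
    frame = np.full((size, size), float(scene.skin_level))
    ry = scene.aperture_ry * aperture
    if ry > 0.2:
        fissure = ((xx - cx) / scene.fissure_rx) ** 2 + (
            (yy - cy) / ry
        ) ** 2 <= 1.0
        frame[fissure] = scene.sclera_level
        iris = (xx - cx) ** 2 + (yy - cy) ** 2 <= scene.iris_radius**2
        frame[fissure & iris] = scene.iris_level
    return frame


def render_sequence(
    schedule: BlinkSchedule,
    scene: SceneConfig | None = None,
    side: Eye = Eye.LEFT,
) -> tuple[EyeSequence, list[BlinkInterval]]:
    """Render the schedule into a noisy uint8 stack plus truth intervals.

    Bit-reproducible for a fixed ``scene.rng_seed``. Core frames show a
    minimal palpebral aperture (the sclera almost fully occluded), so
    their mean intensity in the eye region is markedly lower than in
    open frames.
    """
    scene = scene or SceneConfig()
    rng = np.random.default_rng(scene.rng_seed)
    aperture = _aperture_profile(schedule)
    frames = np.empty((schedule.n_frames, EYE_SIZE, EYE_SIZE), dtype=np.uint8)
    for i, a in enumerate(aperture):
        dx, dy = rng.normal(0.0, scene.jitter_px, size=2)
        clean = _render_frame(a, scene, dx, dy)
        noisy = clean + rng.normal(0.0, scene.noise_sd, size=clean.shape)
        frames[i] = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
    seq = EyeSequence(frames=frames, side=side, fps=schedule.fps)
    return seq, schedule.intervals(side)


def oracle_classifier(schedule: BlinkSchedule, ns: int = DEFAULT_NS):
    """Perfect subsequence classifier derived from the ground truth.

    Votes 1 for a window iff it fully contains some blink's closed core
    (the defining property that makes the accumulator peak reach
    ``ns - core + 1`` on isolated blinks); 0 otherwise. Useful for
    testing the accumulator/watershed/metrics stages independently of
    any learned model.
    """
    return _PositionOracle([b.core_interval for b in schedule.blinks], ns)


class _PositionOracle:
    """Scores windows by their start position against known blink cores.

    Instances are stateful iterators over a sequence's windows: when
    called with a batch of ``k`` windows they score the next ``k``
    window positions (step 1, starting at frame 1), which is exactly the
    order produced by dense-overlap accumulation. ``reset()`` rewinds;
    ``score_start(s)`` scores a single window by its 1-based start.
    """

    def __init__(self, cores: list[tuple[int, int]], ns: int):
        self.cores = cores
        self.ns = ns
        self._next_start = 1

    def reset(self) -> None:
        self._next_start = 1

    def score_start(self, start: int) -> float:
        end = start + self.ns - 1
        for lo, hi in self.cores:
            if start <= lo and hi <= end:
                return 1.0
        return 0.0

    def __call__(self, windows: np.ndarray) -> np.ndarray:
        windows = np.asarray(windows)
        if windows.ndim == 3:
            batch = 1
        else:
            batch = windows.shape[0]
        scores = np.array(
            [
                self.score_start(self._next_start + i)
                for i in range(batch)
            ]
        )
        self._next_start += batch
        return scores[0] if windows.ndim == 3 else scores


def noisy_oracle(oracle: _PositionOracle, flip_prob: float, seed: int = 0):
    """Wrap an oracle so each window vote flips independently with
    probability ``flip_prob`` (< 0.5); deterministic per seed."""
    if not 0 <= flip_prob < 0.5:
        raise ValueError("flip_prob must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)

    class _Noisy:
        def __init__(self):
            self.base = oracle

        def reset(self):
            self.base.reset()

        def __call__(self, windows):
            scores = np.atleast_1d(np.asarray(self.base(windows), dtype=float))
            flips = rng.random(scores.shape) < flip_prob
            out = np.where(flips, 1.0 - scores, scores)
            return out if np.asarray(windows).ndim == 4 else float(out[0])

    return _Noisy()


def export_training_set(
    sequences: list[tuple[EyeSequence, BlinkSchedule]],
    ns: int = DEFAULT_NS,
    seed: int = 0,
    negatives_per_positive: float = 1.0,
) -> LabeledWindowSet:
    """Build a balanced labeled window set from annotated sequences.

    Positive windows start at each annotated blink start; negative
    windows are sampled uniformly from blink-free stretches (never
    overlapping any blink), count-matched to the positives.
    """
    import warnings

    rng = np.random.default_rng(seed)
    pos, neg = [], []
    for seq, schedule in sequences:
        n = seq.n_frames
        blink_mask = np.zeros(n + 1, dtype=bool)
        for b in schedule.blinks:
            blink_mask[b.start : b.end + 1] = True
        for b in schedule.blinks:
            if b.start + ns - 1 <= n:
                pos.append(seq.frames[b.start - 1 : b.start - 1 + ns])
        free_starts = [
            s
            for s in range(1, n - ns + 2)
            if not blink_mask[s : s + ns].any()
        ]
        want = int(round(len(schedule.blinks) * negatives_per_positive))
        if not free_starts:
            warnings.warn("no blink-free stretch of ns frames; skipping negatives")
            continue
        if len(free_starts) < want:
            warnings.warn(
                f"only {len(free_starts)} blink-free starts for {want} "
                "negatives; sampling with replacement"
            )
            chosen = rng.choice(free_starts, size=want, replace=True)
        else:
            chosen = rng.choice(free_starts, size=want, replace=False)
        for s in chosen:
            neg.append(seq.frames[s - 1 : s - 1 + ns])
    windows = np.stack(pos + neg).astype(np.float32)
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return LabeledWindowSet(windows=windows, labels=labels)
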