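"""Dense-overlap prediction accumulator and its segmentation into blinks.

The inference path for one eye sequence is::

    accumulate_predictions -> morphological_close -> watershed_segment
        -> extract_blinks

Every frame is covered by up to ``ns`` overlapping windows (step 1), each
scored by a subsequence classifier. Positive votes are summed per frame
into the accumulator; grayscale closing removes one/two-frame dips that
would over-segment; a 1D watershed on the negated signal splits adjacent
blinks that share elevated values; finally a threshold ``T`` picks the
supra-threshold run around each segment peak as one blink interval.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .types import (
    Accumulator,
    BlinkInterval,
    ClassifierContractError,
    EyeSequence,
    SegmentationConfig,
    SequenceTooShortError,
    SubsequenceWindow,
)

#: A classifier maps one (ns, 48, 48) window -- or a (B, ns, 48, 48)
#: batch -- to blink score(s) in [0, 1].
ClassifierContract = Callable[[np.ndarray], np.ndarray]


def extract_windows(seq: EyeSequence, ns: int) -> list[SubsequenceWindow]:
    """All length-``ns`` windows with step 1 (overlap ``ns - 1``).

    Window ``k`` (1-based start) covers frames ``k .. k + ns - 1``; starts
    run ``1 .. N - ns + 1`` so every frame is covered at least once.
    """
    n = seq.n_frames
    if n < ns:
        raise SequenceTooShortError(
            f"sequence has {n} frames but windows need at least {ns}"
        )
    return [
        SubsequenceWindow(start=k + 1, data=seq.frames[k : k + ns])
        for k in range(n - ns + 1)
    ]


def score_windows(
    clf: ClassifierContract, batch: np.ndarray
) -> np.ndarray:
    """Apply a classifier to a (B, ns, H, W) batch, enforcing its contract."""
    try:
        scores = np.asarray(clf(batch), dtype=float).reshape(-1)
        if scores.shape[0] != batch.shape[0]:
            raise ValueError
    except (ValueError, TypeError):
        # classifier only handles single windows
        scores = np.array([float(clf(w)) for w in batch])
    if scores.size and (scores.min() < 0.0 or scores.max() > 1.0):
        raise ClassifierContractError(
            f"classifier scores outside [0, 1]: range "
            f"[{scores.min():.4g}, {scores.max():.4g}]"
        )
    return scores


def accumulate_predictions(
    seq: EyeSequence,
    clf: ClassifierContract,
    cfg: SegmentationConfig,
    batch_size: int = 64,
) -> Accumulator:
    """Sum per-window blink votes into a per-frame accumulator.

    Each window's score is binarized at ``cfg.binarize_cutoff`` and the
    vote is added to every frame the window covers, so ``values[i]`` is
    the number of positive windows covering frame ``i`` (bounded by
    ``ns``). With ``cfg.soft_votes`` the raw probabilities are summed
    instead.
    """
    windows = extract_windows(seq, cfg.ns)
    n = seq.n_frames
    if hasattr(clf, "reset"):
        clf.reset()  # stateful position-tracking classifiers (oracles)
    votes = np.empty(len(windows))
    for lo in range(0, len(windows), batch_size):
        chunk = windows[lo : lo + batch_size]
        batch = np.stack([w.data for w in chunk])
        votes[lo : lo + len(chunk)] = score_windows(clf, batch)
    if not cfg.soft_votes:
        votes = (votes >= cfg.binarize_cutoff).astype(np.int64)

    # difference-array trick: +v at window start, -v past its end
    diff = np.zeros(n + 1, dtype=votes.dtype)
    starts = np.arange(len(windows))
    np.add.at(diff, starts, votes)
    np.add.at(diff, starts + cfg.ns, -votes)
    values = np.cumsum(diff[:n])
    if not cfg.soft_votes:
        values = values.astype(np.int64)
    return Accumulator(values=values, ns=cfg.ns)


def morphological_close(acc: Accumulator, se_length: int = 3) -> Accumulator:
    """Grayscale closing (erode(dilate(A))) with a flat, centered SE.

    Dilation pads with the signal minimum and erosion with the dilated
    signal's maximum, so the closing is extensive (pointwise >= input)
    and never hallucinates peaks at the sequence ends. Dips narrower
    than ``se_length`` are filled, which is what prevents a jittery
    classifier from splitting one blink into several.
    """
    if se_length < 1 or se_length % 2 == 0:
        raise ValueError(f"se_length must be odd and >= 1, got {se_length}")
    a = np.asarray(acc.values)
    if len(a) == 0 or se_length == 1:
        return Accumulator(values=a.copy(), ns=acc.ns)
    dilated = ndimage.grey_dilation(
        a, size=se_length, mode="constant", cval=a.min()
    )
    closed = ndimage.grey_erosion(
        dilated, size=se_length, mode="constant", cval=dilated.max()
    )
    return Accumulator(values=closed, ns=acc.ns)


def _regional_maxima_plateaus(values: np.ndarray) -> list[tuple[int, int]]:
    """Maximal constant plateaus strictly above both neighbours (0-based,
    inclusive index pairs). Sequence ends count as -inf neighbours."""
    n = len(values)
    plateaus = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        left_lower = i == 0 or values[i - 1] < values[i]
        right_lower = j == n - 1 or values[j + 1] < values[j]
        if left_lower and right_lower:
            plateaus.append((i, j))
        i = j + 1
    return plateaus


def watershed_segment(acc: Accumulator) -> np.ndarray:
    """Label frames by watershed basins of the negated accumulator.

    Returns a length-N integer vector of segment ids ``1 .. K`` where
    ``K`` is the number of regional maxima of the (closed) accumulator.
    Basin boundaries fall at the minimal-value region between two
    consecutive maxima; frames of a boundary minimum plateau are
    assigned to the earlier (left) basin, processed left to right.
    """
    values = np.asarray(acc.values)
    n = len(values)
    labels = np.ones(n, dtype=np.int64)
    maxima = _regional_maxima_plateaus(values)
    if len(maxima) <= 1:
        return labels
    boundaries = []  # index of last frame belonging to the left basin
    for (_, left_end), (right_start, _) in zip(maxima[:-1], maxima[1:]):
        between = values[left_end + 1 : right_start]
        lo = left_end + 1 + int(np.argmin(between))
        # extend across the minimum plateau; plateau goes to the left basin
        hi = lo
        while hi + 1 < right_start and values[hi + 1] == values[lo]:
            hi += 1
        boundaries.append(hi)
    for seg_id, b in enumerate(boundaries, start=1):
        labels[b + 1 :] = seg_id + 1
    return labels


def extract_blinks(
    acc: Accumulator,
    labels: np.ndarray,
    cfg: SegmentationConfig,
    side=None,
) -> list[BlinkInterval]:
    """Threshold watershed segments into blink intervals.

    Per segment: if its peak accumulator value reaches ``threshold_T``,
    emit the maximal contiguous run of supra-threshold frames (within
    the segment) that contains the peak; sub-threshold segments emit
    nothing. Output intervals are sorted and non-overlapping.
    """
    values = np.asarray(acc.values)
    labels = np.asarray(labels)
    if len(labels) != len(values):
        raise ValueError("labels length must match accumulator length")
    kwargs = {} if side is None else {"side": side}
    blinks: list[BlinkInterval] = []
    for seg_id in np.unique(labels):
        idx = np.flatnonzero(labels == seg_id)
        seg_vals = values[idx]
        peak = seg_vals.max()
        if peak < cfg.threshold_T:
            continue
        peak_pos = int(idx[int(np.argmax(seg_vals))])  # earliest peak on ties
        seg_lo, seg_hi = int(idx[0]), int(idx[-1])  # segments are contiguous
        lo = hi = peak_pos
        while lo - 1 >= seg_lo and values[lo - 1] >= cfg.threshold_T:
            lo -= 1
        while hi + 1 <= seg_hi and values[hi + 1] >= cfg.threshold_T:
            hi += 1
        blinks.append(BlinkInterval(start=lo + 1, end=hi + 1, **kwargs))
    return sorted(blinks, key=lambda b: b.start)


def detect_blinks(
    seq: EyeSequence,
    clf: ClassifierContract,
    cfg: SegmentationConfig | None = None,
) -> list[BlinkInterval]:
    """Full inference for one eye: accumulate, close, watershed, threshold."""
    if cfg is None:
        cfg = SegmentationConfig()
    acc = accumulate_predictions(seq, clf, cfg)
    closed = morphological_close(acc, cfg.se_length)
    labels = watershed_segment(closed)
    return extract_blinks(closed, labels, cfg, side=seq.side)


def blink_mask(
    intervals: Sequence[BlinkInterval], n_frames: int
) -> np.ndarray:
    """Binary per-frame mask (length ``n_frames``) from blink intervals."""
    mask = np.zeros(n_frames, dtype=np.int64)
    for b in intervals:
        mask[b.start - 1 : min(b.end, n_frames)] = 1
    return mask
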