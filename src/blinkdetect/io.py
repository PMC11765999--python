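"""Reading and writing the pipeline's on-disk formats.

Annotations travel as CSV with header ``eye,start_frame,end_frame``
(1-based inclusive). Frame stacks are multi-page grayscale TIFFs or
directories of per-frame images (lexicographic order); inputs that are
not 48x48 are resized with a logged warning. Run configuration is YAML.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml
from skimage.transform import resize

from .types import EYE_SIZE, BlinkInterval, Eye, EyeSequence, SegmentationConfig

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["eye", "start_frame", "end_frame"]


def read_annotations(path: str | Path) -> list[BlinkInterval]:
    """Parse a blink annotation CSV, validating every row.

    Raises ``ValueError`` naming the offending line for malformed rows,
    unknown eye labels, or ``end < start``.
    """
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # header is line 1
        try:
            eye = Eye(str(row.eye).strip().lower())
        except ValueError:
            raise ValueError(
                f"{path}, line {line}: unknown eye label {row.eye!r}"
            ) from None
        try:
            start, end = int(row.start_frame), int(row.end_frame)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}, line {line}: non-integer frame index"
            ) from None
        try:
            records.append(BlinkInterval(start=start, end=end, side=eye))
        except ValueError as exc:
            raise ValueError(f"{path}, line {line}: {exc}") from None
    return records


def write_annotations(records: list[BlinkInterval], path: str | Path) -> None:
    """Write intervals as a sorted annotation CSV (byte-stable)."""
    rows = sorted(records, key=lambda b: (b.side.value, b.start, b.end))
    df = pd.DataFrame(
        [(b.side.value, b.start, b.end) for b in rows],
        columns=ANNOTATION_COLUMNS,
    )
    df.to_csv(path, index=False)


def write_accumulator(values: np.ndarray, path: str | Path) -> None:
    """Dump an accumulator as ``frame,value`` CSV for debugging/plots."""
    df = pd.DataFrame(
        {"frame": np.arange(1, len(values) + 1), "value": values}
    )
    df.to_csv(path, index=False)


def _to_grayscale_uint8(frames: np.ndarray, source: str) -> np.ndarray:
    frames = np.asarray(frames)
    if frames.ndim == 4:  # RGB(A) pages -> luminance
        frames = frames[..., :3].mean(axis=-1)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(f"{source}: cannot interpret shape {frames.shape}")
    if frames.dtype != np.uint8:
        peak = frames.max() if frames.size else 1.0
        if peak > 255:
            frames = frames * (255.0 / peak)
        frames = np.clip(np.rint(frames.astype(float)), 0, 255).astype(np.uint8)
    if frames.shape[1:] != (EYE_SIZE, EYE_SIZE):
        logger.warning(
            "%s: resizing frames from %sx%s to %dx%d",
            source, frames.shape[1], frames.shape[2], EYE_SIZE, EYE_SIZE,
        )
        frames = np.stack(
            [
                np.clip(
                    np.rint(
                        resize(f.astype(float), (EYE_SIZE, EYE_SIZE),
                               preserve_range=True, anti_aliasing=True)
                    ), 0, 255,
                ).astype(np.uint8)
                for f in frames
            ]
        )
    return frames


def read_stack(path: str | Path, side: Eye = Eye.LEFT, fps: float = 25.0) -> EyeSequence:
    """Load an eye stack from a multi-page TIFF or an image directory."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in {".png", ".pgm", ".tif", ".tiff", ".jpg", ".jpeg"}
        )
        if not files:
            raise ValueError(f"{path}: no image files found")
        frames = np.stack([np.atleast_2d(iio.imread(f)) for f in files])
    else:
        frames = tifffile.imread(path)
    frames = _to_grayscale_uint8(frames, str(path))
    if frames.shape[0] == 0:
        raise ValueError(f"{path}: zero frames")
    return EyeSequence(frames=frames, side=side, fps=fps)


def write_stack(seq: EyeSequence, path: str | Path) -> None:
    """Write a sequence as a multi-page grayscale TIFF."""
    # 3-frame stacks would otherwise be guessed as RGB planes
    tifffile.imwrite(path, seq.frames.astype(np.uint8), photometric="minisblack")


@dataclass
class RunConfig:
    """All pipeline constants for one run, serializable to YAML."""

    ns: int = 12
    se_length: int = 3
    threshold_T: float = 6
    binarize_cutoff: float = 0.5
    iou_threshold: float = 0.2
    fps: float = 25.0
    rng_seed: int = 0
    model_path: str | None = None
    architecture: str = "cnn3d"

    def segmentation(self) -> SegmentationConfig:
        return SegmentationConfig(
            ns=self.ns,
            se_length=self.se_length,
            threshold_T=self.threshold_T,
            binarize_cutoff=self.binarize_cutoff,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def provenance_block(config: RunConfig) -> dict:
    """Machine-readable echo of the constants a run used."""
    import blinkdetect

    return {
        "blinkdetect_version": blinkdetect.__version__,
        "numpy_version": np.__version__,
        "config": asdict(config),
    }
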