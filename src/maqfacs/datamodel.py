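"""Core data types for facial action-unit (AU) video datasets.

The package works in the MaqFACS domain: every video frame carries one
harmonized AU class for the upper face and one for the lower face.  The
six classifier targets are

* upper face: ``UpperNone`` (no coded action), ``AU1+2`` (brow raiser),
  ``AU43_5`` (eye closure / blink, merged — they differ only in duration);
* lower face: ``AU25+26`` (lips part + jaw drop), ``AU25+26+16``
  (+ lower-lip depressor), ``AU25+26+18i`` (+ true pucker).

Frames whose coded content falls outside these targets map to the
sentinel classes ``OtherUpper`` / ``OtherLower`` (kept for behavioral
reporting, never used as classifier targets), and frames with no lower
coding map to ``LowerNone``.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)


class Region(str, enum.Enum):
    UPPER = "upper"
    LOWER = "lower"


class AUClass(str, enum.Enum):
    """Harmonized per-region AU classes (targets + sentinels)."""

    UPPER_NONE = "UpperNone"
    AU1_2 = "AU1+2"
    AU43_5 = "AU43_5"
    OTHER_UPPER = "OtherUpper"

    LOWER_NONE = "LowerNone"
    AU25_26 = "AU25+26"
    AU25_26_16 = "AU25+26+16"
    AU25_26_18I = "AU25+26+18i"
    OTHER_LOWER = "OtherLower"

    @property
    def region(self) -> Region:
        if self in _UPPER_ALL:
            return Region.UPPER
        return Region.LOWER

    @property
    def is_target(self) -> bool:
        return self in UPPER_TARGETS or self in LOWER_TARGETS


# Fixed class orders: used for confusion-matrix layout and deterministic
# tie-breaking in the classifiers.
UPPER_TARGETS: tuple[AUClass, ...] = (AUClass.UPPER_NONE, AUClass.AU1_2, AUClass.AU43_5)
LOWER_TARGETS: tuple[AUClass, ...] = (
    AUClass.AU25_26,
    AUClass.AU25_26_16,
    AUClass.AU25_26_18I,
)
_UPPER_ALL = frozenset(UPPER_TARGETS) | {AUClass.OTHER_UPPER}
_LOWER_ALL = frozenset(LOWER_TARGETS) | {AUClass.OTHER_LOWER, AUClass.LOWER_NONE}

#: raw codes treated as eye closure (AU43 eye closure and AU45 blink are
#: merged since they differ only in movement duration)
_EYE_CLOSURE_CODES = frozenset({"AU43", "AU45", "AU43_5"})


def target_classes(region: Region | str) -> tuple[AUClass, ...]:
    """The three classifier target classes of a facial region, in fixed order."""
    return UPPER_TARGETS if Region(region) is Region.UPPER else LOWER_TARGETS


def neutral_class(region: Region | str) -> AUClass:
    return AUClass.UPPER_NONE if Region(region) is Region.UPPER else AUClass.LOWER_NONE


def harmonize_labels(raw_codes: Iterable[str], region: Region | str) -> AUClass:
    """Map a set of raw AU codes for one frame/region to its harmonized class.

    Total and deterministic.  Upper face: an empty set is neutral
    (``UpperNone``); any nonempty subset of the eye-closure codes maps to
    ``AU43_5``; exactly ``{AU1+2}`` maps to ``AU1+2``; everything else
    (including co-occurring brow raise + eye closure, which the target
    taxonomy cannot express) maps to ``OtherUpper`` and is logged.  Lower
    face: ``AU12`` is removed before matching (excluded from analysis for
    being too infrequent in the training corpus); the three exact
    combinations map to their classes, an empty residual set to
    ``LowerNone``, anything else to ``OtherLower``.
    """
    region = Region(region)
    codes = {str(c) for c in raw_codes if str(c)}
    if region is Region.UPPER:
        if not codes:
            return AUClass.UPPER_NONE
        if codes <= _EYE_CLOSURE_CODES:
            return AUClass.AU43_5
        if codes == {"AU1+2"}:
            return AUClass.AU1_2
        if codes & _EYE_CLOSURE_CODES or "AU1+2" in codes:
            logger.debug("multi-AU upper-face frame %s mapped to OtherUpper", codes)
        return AUClass.OTHER_UPPER
    codes.discard("AU12")
    if not codes:
        return AUClass.LOWER_NONE
    if codes == {"AU25", "AU26"}:
        return AUClass.AU25_26
    if codes == {"AU25", "AU26", "AU16"}:
        return AUClass.AU25_26_16
    if codes == {"AU25", "AU26", "AU18i"}:
        return AUClass.AU25_26_18I
    return AUClass.OTHER_LOWER


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert a frame to single-channel intensity via fixed luma weights.

    RGB channels are combined as 0.299 R + 0.587 G + 0.114 B; an
    already-grayscale 2-D input is returned unchanged (as float).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[2] == 1:
        return frame[:, :, 0]
    if frame.ndim == 3 and frame.shape[2] == 3:
        return frame @ np.array([0.299, 0.587, 0.114])
    raise ValueError(
        f"expected a 2-D grayscale or 3-channel RGB frame, got shape {frame.shape}"
    )


@dataclass(frozen=True)
class FrameLabel:
    """One coded (video, frame, region) row of a label table."""

    video_id: str
    frame_index: int
    region: Region
    raw_codes: frozenset[str]
    intensity: Optional[str] = None  # parsed but not used by classification

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError(f"negative frame index {self.frame_index}")


@dataclass
class LabeledVideo:
    """Frames of one video plus per-frame, per-region harmonized AU classes."""

    video_id: str
    subject_id: str
    species: str  # "rhesus" | "fascicularis" | "synthetic"
    frames: np.ndarray  # (n_frames, height, width) float, native 0-255 scale
    fps: float
    upper: list[AUClass] = field(default_factory=list)
    lower: list[AUClass] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (n, h, w), got {self.frames.shape}")
        n = len(self.frames)
        if not self.upper:
            self.upper = [AUClass.UPPER_NONE] * n
        if not self.lower:
            self.lower = [AUClass.LOWER_NONE] * n
        if len(self.upper) != n or len(self.lower) != n:
            raise ValueError("labels must cover every frame for both regions")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]

    def labels(self, region: Region | str) -> list[AUClass]:
        return self.upper if Region(region) is Region.UPPER else self.lower

    def neutral_indices(self) -> np.ndarray:
        """Frames neutral in both regions (no coded action anywhere)."""
        mask = [
            u is AUClass.UPPER_NONE and l is AUClass.LOWER_NONE
            for u, l in zip(self.upper, self.lower)
        ]
        return np.flatnonzero(mask)


@dataclass
class Dataset:
    """A collection of labeled videos with unique ids and subject metadata."""

    videos: list[LabeledVideo]

    def __post_init__(self) -> None:
        ids = [v.video_id for v in self.videos]
        if len(set(ids)) != len(ids):
            raise ValueError("video_ids must be unique")
        for v in self.videos:
            if not v.subject_id:
                raise ValueError(f"video {v.video_id} lacks a subject_id")

    @property
    def subjects(self) -> list[str]:
        return sorted({v.subject_id for v in self.videos})

    def videos_of(self, subject_id: str) -> list[LabeledVideo]:
        return [v for v in self.videos if v.subject_id == subject_id]

    def __iter__(self):
        return iter(self.videos)

    def __len__(self) -> int:
        return len(self.videos)


def attach_labels(video: LabeledVideo, labels: Sequence[FrameLabel]) -> LabeledVideo:
    """Fill a video's per-frame classes from parsed label rows.

    Frames absent from the table stay at the region-neutral class.
    """
    for lab in labels:
        if lab.video_id != video.video_id:
            continue
        if lab.frame_index >= video.n_frames:
            raise IndexError(
                f"label frame {lab.frame_index} >= frame count {video.n_frames} "
                f"in video {video.video_id}"
            )
        cls = harmonize_labels(lab.raw_codes, lab.region)
        video.labels(lab.region)[lab.frame_index] = cls
    return video
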