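"""Landmark-based affine alignment of face video into a common frame.

Seven landmarks (two corners per eye, two mouth corners, mouth center)
are annotated once per video on the mean of its neutral frames.  A
single least-squares affine transform maps them to fixed reference
positions expressed as fractions of the frame size, and that one
transform is applied to every frame of the video, correcting camera
pose and seating differences between recordings.

Coordinates are 0-based with x = column, y = row, origin at the
top-left, continuous coordinates at pixel centers.  Warping uses
inverse-mapped bilinear resampling with zero fill outside the source.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from skimage.transform import AffineTransform as _SkAffine
from skimage.transform import warp as _sk_warp

from .datamodel import LabeledVideo

LANDMARK_NAMES: tuple[str, ...] = (
    "left_eye_outer",
    "left_eye_inner",
    "right_eye_inner",
    "right_eye_outer",
    "mouth_left",
    "mouth_right",
    "mouth_center",
)

#: reference positions as (x, y) fractions of (width, height)
REFERENCE_FRACTIONS: dict[str, tuple[float, float]] = {
    "left_eye_outer": (0.42, 0.30),
    "left_eye_inner": (0.48, 0.30),
    "right_eye_inner": (0.52, 0.30),
    "right_eye_outer": (0.58, 0.30),
    "mouth_left": (0.44, 0.55),
    "mouth_right": (0.56, 0.55),
    "mouth_center": (0.50, 0.50),
}


@dataclass(frozen=True)
class LandmarkSet:
    """The 7 named facial points of one video, in pixel coordinates."""

    points: Mapping[str, tuple[float, float]]
    image_size: tuple[int, int] | None = None  # (width, height), optional

    def __post_init__(self) -> None:
        missing = set(LANDMARK_NAMES) - set(self.points)
        if missing:
            raise ValueError(f"missing landmarks: {sorted(missing)}")
        if self.image_size is not None:
            w, h = self.image_size
            for name in LANDMARK_NAMES:
                x, y = self.points[name]
                if not (0 <= x < w and 0 <= y < h):
                    raise ValueError(
                        f"landmark {name} at ({x}, {y}) outside {w}x{h} image"
                    )

    def as_array(self) -> np.ndarray:
        """(7, 2) array of (x, y) in the canonical landmark order."""
        return np.array([self.points[n] for n in LANDMARK_NAMES], dtype=float)


@dataclass(frozen=True)
class AffineTransform:
    """2x3 matrix mapping source (x, y, 1) to destination (x', y')."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError(f"affine matrix must be 2x3, got {m.shape}")
        if abs(np.linalg.det(m[:, :2])) <= 1e-12:
            raise ValueError("affine transform is singular")
        object.__setattr__(self, "matrix", m)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 2) array of (x, y) points."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    def inverse(self) -> "AffineTransform":
        full = np.vstack([self.matrix, [0.0, 0.0, 1.0]])
        return AffineTransform(np.linalg.inv(full)[:2])

    @staticmethod
    def identity() -> "AffineTransform":
        return AffineTransform(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))


def reference_landmarks(width: int, height: int) -> LandmarkSet:
    """Reference landmark positions for a frame of the given size."""
    if width < 1 or height < 1:
        raise ValueError(f"non-positive frame size {width}x{height}")
    pts = {
        name: (fx * width, fy * height)
        for name, (fx, fy) in REFERENCE_FRACTIONS.items()
    }
    return LandmarkSet(pts, image_size=(width, height))


def mean_neutral_image(video: LabeledVideo) -> np.ndarray:
    """Pixel-wise mean over all frames neutral in both face regions."""
    idx = video.neutral_indices()
    if idx.size == 0:
        raise ValueError(f"video {video.video_id} has no neutral frames")
    return video.frames[idx].mean(axis=0)


def estimate_affine(src: LandmarkSet, dst: LandmarkSet) -> AffineTransform:
    """Least-squares affine mapping src landmarks onto dst landmarks.

    The 7 correspondences over-determine the 6 affine parameters;
    ordinary least squares gives the unique minimizer when the source
    points are not collinear.  For affine-consistent correspondences the
    fit is exact to machine precision.
    """
    s = src.as_array()
    d = dst.as_array()
    design = np.column_stack([s, np.ones(len(s))])  # (7, 3)
    if np.linalg.matrix_rank(design, tol=1e-9) < 3:
        raise ValueError("source landmarks are collinear; affine is degenerate")
    sol, *_ = np.linalg.lstsq(design, d, rcond=None)  # (3, 2)
    return AffineTransform(sol.T)


def warp_frame(
    frame: np.ndarray,
    t: AffineTransform,
    out_size: tuple[int, int] | None = None,
) -> np.ndarray:
    """Apply an affine transform to a frame (bilinear, zero fill).

    ``out_size`` is (width, height); defaults to the input size.  The
    output pixel at (x', y') samples the input at t^-1 (x', y').
    """
    frame = np.asarray(frame, dtype=float)
    if out_size is None:
        out_size = (frame.shape[1], frame.shape[0])
    w, h = out_size
    inv = np.vstack([t.inverse().matrix, [0.0, 0.0, 1.0]])
    return _sk_warp(
        frame,
        inverse_map=_SkAffine(matrix=inv),
        output_shape=(h, w),
        order=1,
        mode="constant",
        cval=0.0,
        preserve_range=True,
    )


def align_video(video: LabeledVideo, landmarks: LandmarkSet) -> LabeledVideo:
    """Warp every frame of a video into the reference coordinate frame.

    One transform is estimated per video — from the landmarks annotated
    on its mean-neutral image to the reference positions for the frame
    size — and applied identically to all frames.  Labels carry over.
    """
    h, w = video.frame_shape
    t = estimate_affine(landmarks, reference_landmarks(w, h))
    warped = np.stack([warp_frame(f, t, (w, h)) for f in video.frames])
    return LabeledVideo(
        video_id=video.video_id,
        subject_id=video.subject_id,
        species=video.species,
        frames=warped,
        fps=video.fps,
        upper=list(video.upper),
        lower=list(video.lower),
    )
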