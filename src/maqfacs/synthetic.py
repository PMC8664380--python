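"""Synthetic head-fixed face video with parametric AU-like deformations.

The generator renders schematic frontal macaque faces — a smooth face
blob, eyes with brows, a nose and a mouth — whose features deform
according to the harmonized AU classes:

* ``AU1+2``   brows displaced upward;
* ``AU43_5``  eye aperture shrunk toward zero (closure);
* ``AU25+26`` mouth aperture opened (lips part + jaw drop);
* ``+16``     a lower-lip band pushed downward;
* ``+18i``    mouth corners pulled inward with protrusion shading.

Faces are schematic 2-D renderings, not photorealistic: the recognition
pipeline consumes intensity structure, not realism.  Each subject gets
deterministic appearance offsets (intensity, feature scale); each video
gets a pose offset (rotation / scale / translation) applied to every
frame, so the alignment stage has real work to do; AU labels arrive in
temporally contiguous episodes as in real behavioral coding.  In the
canonical (pose-free) geometry the landmarks sit exactly at the
reference positions, and upper-face deformations are confined to the
upper ROI rows (and vice versa), which enables exact region-locality
tests at zero noise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np

from .alignment import (
    AffineTransform,
    LandmarkSet,
    reference_landmarks,
    warp_frame,
)
from .datamodel import AUClass, Dataset, LabeledVideo, Region
from .preprocess import ROISpec


@dataclass(frozen=True)
class PoseJitter:
    """Per-video camera-pose offset ranges (uniform, symmetric)."""

    rotation_deg: float = 5.0
    scale: float = 0.05
    translation_px: float = 10.0


def _default_magnitudes(image_size: tuple[int, int]) -> dict[AUClass, float]:
    # pixel displacements proportional to frame height; at the default
    # 800x700 size these are ~18/12/30/18/14 px
    h = image_size[1]
    return {
        AUClass.AU1_2: 0.026 * h,
        AUClass.AU43_5: 0.017 * h,
        AUClass.AU25_26: 0.043 * h,
        AUClass.AU25_26_16: 0.026 * h,
        AUClass.AU25_26_18I: 0.020 * h,
    }


@dataclass
class SyntheticConfig:
    image_size: tuple[int, int] = (800, 700)  # (width, height)
    n_subjects: int = 5
    videos_per_subject: int = 3
    frames_per_video: int = 300
    fps: float = 30.0
    upper_frequencies: dict[AUClass, float] = field(
        default_factory=lambda: {
            AUClass.UPPER_NONE: 0.77,
            AUClass.AU43_5: 0.17,
            AUClass.AU1_2: 0.06,
        }
    )
    lower_frequencies: dict[AUClass, float] = field(
        default_factory=lambda: {
            AUClass.LOWER_NONE: 0.40,
            AUClass.AU25_26: 0.30,
            AUClass.AU25_26_18I: 0.22,
            AUClass.AU25_26_16: 0.08,
        }
    )
    deformation_magnitudes: Optional[dict[AUClass, float]] = None  # px
    noise_sd: float = 2.0  # additive Gaussian intensity noise
    pose_jitter: PoseJitter = field(default_factory=PoseJitter)
    mean_episode_frames: float = 6.0
    min_au_episode_frames: int = 3
    neutral_lead_frames: int = 3  # every video starts at rest
    seed: int = 0

    def __post_init__(self) -> None:
        for freqs in (self.upper_frequencies, self.lower_frequencies):
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"class frequencies sum to {total}, not 1")
        if self.deformation_magnitudes is None:
            self.deformation_magnitudes = _default_magnitudes(self.image_size)
        if any(m < 0 for m in self.deformation_magnitudes.values()):
            raise ValueError("deformation magnitudes must be >= 0")


@dataclass
class GroundTruth:
    poses: dict[str, AffineTransform]  # video_id -> true pose transform
    landmarks: dict[str, LandmarkSet]  # video_id -> true landmark positions


def default_rois(image_size: tuple[int, int]) -> dict[Region, ROISpec]:
    """Upper/lower ROIs matching the rendered face template geometry."""
    w, h = image_size
    split = int(0.42 * h)
    return {
        Region.UPPER: ROISpec(Region.UPPER, (0, 0, w, split)),
        Region.LOWER: ROISpec(Region.LOWER, (0, split, w, h - split)),
    }


def _subject_params(subject_id: str) -> dict[str, float]:
    rng = np.random.default_rng(zlib.crc32(subject_id.encode()) % (2**31))
    return {
        "base": 160.0 + rng.uniform(-15.0, 15.0),
        "feature_gain": rng.uniform(0.85, 1.15),
        "eye_scale": rng.uniform(0.9, 1.1),
        "brow_offset": rng.uniform(-0.01, 0.01),  # fraction of height
        "mouth_scale": rng.uniform(0.9, 1.1),
    }


def _soft_ellipse(
    xx: np.ndarray, yy: np.ndarray, cx: float, cy: float, a: float, b: float
) -> np.ndarray:
    """Soft-edged ellipse indicator (1 inside, smooth ~2 px falloff)."""
    d = ((xx - cx) / max(a, 1e-6)) ** 2 + ((yy - cy) / max(b, 1e-6)) ** 2
    return 1.0 / (1.0 + np.exp(np.clip(4.0 * (d - 1.0), -60.0, 60.0)))


def render_face(
    config: SyntheticConfig,
    subject_id: str,
    upper_class: AUClass,
    lower_class: AUClass,
    phase: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, LandmarkSet]:
    """Render one canonical (pose-free) face frame plus its true landmarks.

    ``phase`` in [0, 1] scales the AU deformation.  Noise is added only
    when ``config.noise_sd > 0`` and an ``rng`` is supplied (or a fresh
    unseeded one is NOT created: rendering is deterministic without one).
    """
    if upper_class.region is not Region.UPPER:
        raise ValueError(f"{upper_class.value} is not an upper-face class")
    if lower_class.region is not Region.LOWER:
        raise ValueError(f"{lower_class.value} is not a lower-face class")
    w, h = config.image_size
    mags = config.deformation_magnitudes
    p = _subject_params(subject_id)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    img = np.full((h, w), 25.0)
    img += (p["base"] - 25.0) * _soft_ellipse(
        xx, yy, 0.5 * w, 0.45 * h, 0.34 * w, 0.42 * h
    )

    upper = np.zeros((h, w))
    lower = np.zeros((h, w))
    gain = p["feature_gain"]

    # --- upper face: brows + eyes -------------------------------------
    brow_y = (0.22 + p["brow_offset"]) * h
    if upper_class is AUClass.AU1_2:
        brow_y -= phase * mags.get(AUClass.AU1_2, 0.0)
    eye_b0 = 0.045 * h * p["eye_scale"]
    eye_b = eye_b0
    if upper_class is AUClass.AU43_5:
        eye_b = max(eye_b0 - phase * mags.get(AUClass.AU43_5, 0.0), 0.15)
    for cx in (0.45 * w, 0.55 * w):
        upper += 95.0 * gain * _soft_ellipse(xx, yy, cx, 0.30 * h, 0.035 * w, eye_b)
        upper += 70.0 * gain * _soft_ellipse(
            xx, yy, cx, brow_y, 0.05 * w, 0.012 * h
        )

    # --- lower face: nose + mouth -------------------------------------
    lower += 40.0 * gain * _soft_ellipse(
        xx, yy, 0.5 * w, 0.46 * h, 0.03 * w, 0.02 * h
    )
    mouth_y = 0.53 * h
    half_width = 0.06 * w * p["mouth_scale"]
    aperture = 0.006 * h  # closed lips: a thin line
    if lower_class is not AUClass.LOWER_NONE and lower_class is not AUClass.OTHER_LOWER:
        aperture += phase * mags.get(AUClass.AU25_26, 0.0)
    if lower_class is AUClass.AU25_26_18I:
        half_width = max(
            half_width - phase * mags.get(AUClass.AU25_26_18I, 0.0), 0.02 * w
        )
        # pucker protrusion shading: bright blob at the mouth center
        sigma = max(mags.get(AUClass.AU25_26_18I, 1.0), 1.0)
        lower -= (
            55.0
            * phase
            * np.exp(
                -(((xx - 0.5 * w) ** 2 + (yy - (mouth_y - 0.5 * sigma)) ** 2))
                / (2.0 * sigma**2)
            )
        )
    mouth_cy = mouth_y + 0.5 * aperture
    lower += 90.0 * gain * _soft_ellipse(
        xx, yy, 0.5 * w, mouth_cy, half_width, max(0.5 * aperture, 0.004 * h)
    )
    if lower_class is AUClass.AU25_26_16:
        lip_y = mouth_cy + 0.5 * aperture + phase * mags.get(
            AUClass.AU25_26_16, 0.0
        )
        lower += 85.0 * gain * _soft_ellipse(
            xx, yy, 0.5 * w, lip_y, 1.1 * half_width, 0.025 * h
        )

    # confine each region's features to its ROI rows so deformations are
    # exactly region-local at zero noise
    split = int(0.42 * h)
    upper[split:, :] = 0.0
    lower[:split, :] = 0.0
    img -= upper
    img -= lower

    if config.noise_sd > 0 and rng is not None:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 255.0)
    landmarks = reference_landmarks(w, h)
    return img, landmarks


def _pose_transform(
    rng: np.random.Generator, config: SyntheticConfig
) -> AffineTransform:
    w, h = config.image_size
    jit = config.pose_jitter
    theta = np.deg2rad(rng.uniform(-jit.rotation_deg, jit.rotation_deg))
    s = rng.uniform(1.0 - jit.scale, 1.0 + jit.scale)
    tx = rng.uniform(-jit.translation_px, jit.translation_px)
    ty = rng.uniform(-jit.translation_px, jit.translation_px)
    c, d = np.cos(theta), np.sin(theta)
    lin = s * np.array([[c, -d], [d, c]])
    center = np.array([0.5 * w, 0.5 * h])
    trans = center + np.array([tx, ty]) - lin @ center
    return AffineTransform(np.column_stack([lin, trans]))


def _label_stream(
    n: int,
    frequencies: dict[AUClass, float],
    neutral: AUClass,
    rng: np.random.Generator,
    config: SyntheticConfig,
) -> list[AUClass]:
    classes = list(frequencies)
    probs = np.array([frequencies[c] for c in classes])
    labels: list[AUClass] = [neutral] * min(config.neutral_lead_frames, n)
    p_geom = 1.0 / config.mean_episode_frames
    while len(labels) < n:
        c = classes[rng.choice(len(classes), p=probs)]
        length = int(rng.geometric(p_geom))
        if c is not neutral:
            length = max(length, config.min_au_episode_frames)
        labels.extend([c] * length)
    labels = labels[:n]
    # an AU episode cut short by the video end reverts to neutral so that
    # every emitted AU episode spans at least min_au_episode_frames
    tail = 0
    for cls in reversed(labels):
        if cls is labels[-1]:
            tail += 1
        else:
            break
    if (
        labels
        and labels[-1] is not neutral
        and tail < config.min_au_episode_frames
    ):
        labels[-tail:] = [neutral] * tail
    return labels


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[Dataset, GroundTruth]:
    """Generate a labeled multi-subject dataset with known ground truth.

    Per video, one pose transform is drawn and applied to every frame;
    the returned ground truth holds each video's true pose and the true
    landmark positions (the pose applied to the reference landmarks).
    Bit-identical for a fixed config seed.
    """
    w, h = config.image_size
    videos: list[LabeledVideo] = []
    poses: dict[str, AffineTransform] = {}
    landmarks: dict[str, LandmarkSet] = {}
    ref_pts = reference_landmarks(w, h).as_array()
    for si in range(config.n_subjects):
        subject_id = f"S{si:02d}"
        for vi in range(config.videos_per_subject):
            video_id = f"{subject_id}_V{vi:02d}"
            rng = np.random.default_rng([config.seed % (2**31), si, vi])
            pose = _pose_transform(rng, config)
            upper = _label_stream(
                config.frames_per_video,
                config.upper_frequencies,
                AUClass.UPPER_NONE,
                rng,
                config,
            )
            lower = _label_stream(
                config.frames_per_video,
                config.lower_frequencies,
                AUClass.LOWER_NONE,
                rng,
                config,
            )
            cache: dict[tuple[AUClass, AUClass], np.ndarray] = {}
            frames = np.empty((config.frames_per_video, h, w))
            for fi, (uc, lc) in enumerate(zip(upper, lower)):
                key = (uc, lc)
                if key not in cache:
                    canonical, _ = render_face(config, subject_id, uc, lc)
                    cache[key] = warp_frame(canonical, pose, (w, h))
                frame = cache[key]
                if config.noise_sd > 0:
                    frame = np.clip(
                        frame + rng.normal(0.0, config.noise_sd, frame.shape),
                        0.0,
                        255.0,
                    )
                frames[fi] = frame
            videos.append(
                LabeledVideo(
                    video_id=video_id,
                    subject_id=subject_id,
                    species="synthetic",
                    frames=frames,
                    fps=config.fps,
                    upper=upper,
                    lower=lower,
                )
            )
            poses[video_id] = pose
            true_pts = pose.apply(ref_pts)
            landmarks[video_id] = LandmarkSet(
                {
                    name: tuple(pt)
                    for name, pt in zip(
                        reference_landmarks(w, h).points, true_pts
                    )
                },
                image_size=None,
            )
    return Dataset(videos), GroundTruth(poses=poses, landmarks=landmarks)


_RAW_CODES: dict[AUClass, tuple[str, ...]] = {
    AUClass.AU1_2: ("AU1+2",),
    AUClass.AU43_5: ("AU43",),
    AUClass.AU25_26: ("AU25", "AU26"),
    AUClass.AU25_26_16: ("AU25", "AU26", "AU16"),
    AUClass.AU25_26_18I: ("AU25", "AU26", "AU18i"),
}


def write_dataset(
    dataset: Dataset,
    ground_truth: GroundTruth,
    out_dir: str | Path,
    config: SyntheticConfig,
) -> None:
    """Emit the on-disk formats the loading pipeline consumes.

    Per video: a directory of 8-bit PNG frames plus a manifest; dataset
    level: one label table, one landmark file and an ROI config.
    """
    from .datamodel import FrameLabel
    from .io import write_label_table, write_landmarks, write_manifest
    from .preprocess import write_roi_config

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels: list[FrameLabel] = []
    for video in dataset:
        vdir = out_dir / video.video_id
        vdir.mkdir(exist_ok=True)
        for fi, frame in enumerate(video.frames):
            iio.imwrite(
                vdir / f"frame_{fi:05d}.png",
                np.clip(np.round(frame), 0, 255).astype(np.uint8),
            )
        write_manifest(
            {
                "video_id": video.video_id,
                "subject_id": video.subject_id,
                "species": video.species,
                "fps": video.fps,
            },
            vdir / "manifest.txt",
        )
        for region in (Region.UPPER, Region.LOWER):
            for fi, cls in enumerate(video.labels(region)):
                codes = _RAW_CODES.get(cls)
                if codes:
                    labels.append(
                        FrameLabel(video.video_id, fi, region, frozenset(codes))
                    )
    write_label_table(labels, out_dir / "labels.csv")
    write_landmarks(ground_truth.landmarks, out_dir / "landmarks.csv")
    write_roi_config(default_rois(config.image_size), out_dir / "rois.txt")
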