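"""ROI cropping, optimal-neutral selection, delta-images and databases.

After alignment each frame is cropped to rectangular upper-face and
lower-face regions of interest (ROIs).  For every video one "optimal"
neutral frame is selected, and delta-images — signed differences
frame minus optimal neutral — are computed; these cancel per-video
texture and illumination and retain the facial deformation itself.
Flattened delta-images are stacked into a row-per-image database with
per-row provenance metadata.

Pixel values stay on the native 0-255 float scale throughout: the
eigenvalue elimination threshold downstream is scale-dependent.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .datamodel import AUClass, LabeledVideo, Region
from .alignment import mean_neutral_image


@dataclass(frozen=True)
class ROISpec:
    """Half-open rectangle [x0, x0+w) x [y0, y0+h) in aligned-image pixels."""

    region: Region
    rect: tuple[int, int, int, int]  # (x0, y0, width, height)

    def __post_init__(self) -> None:
        x0, y0, w, h = self.rect
        if w < 1 or h < 1:
            raise ValueError(f"ROI must be at least 1x1, got {self.rect}")
        if x0 < 0 or y0 < 0:
            raise ValueError(f"ROI origin must be non-negative, got {self.rect}")

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of the cropped images."""
        return (self.rect[3], self.rect[2])

    @property
    def n_pixels(self) -> int:
        return self.rect[2] * self.rect[3]


@dataclass(frozen=True)
class DeltaImage:
    """Signed difference between a frame ROI and the optimal-neutral ROI."""

    values: np.ndarray
    source: tuple[str, int]  # (video_id, frame_index)
    region: Region


@dataclass(frozen=True)
class RowMeta:
    video_id: str
    frame_index: int
    subject_id: str
    au_class: AUClass


@dataclass
class ImageDatabase:
    """Row-per-delta-image matrix with per-row provenance.

    ``matrix`` is (n_images, n_pixels); rows are row-major flattenings of
    delta-images, ordered by video then frame.
    """

    matrix: np.ndarray
    rows_meta: list[RowMeta]
    region: Region
    roi_shape: tuple[int, int]  # (height, width)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n, p = self.matrix.shape
        if p != self.roi_shape[0] * self.roi_shape[1]:
            raise ValueError(
                f"row length {p} != ROI pixel count "
                f"{self.roi_shape[0] * self.roi_shape[1]}"
            )
        if len(self.rows_meta) != n:
            raise ValueError("rows_meta length must equal the row count")

    @property
    def n_images(self) -> int:
        return self.matrix.shape[0]

    def labels(self) -> list[AUClass]:
        return [m.au_class for m in self.rows_meta]

    def class_counts(self) -> dict[AUClass, int]:
        counts: dict[AUClass, int] = {}
        for m in self.rows_meta:
            counts[m.au_class] = counts.get(m.au_class, 0) + 1
        return counts

    def rows_where(self, **fields) -> np.ndarray:
        """Row indices whose metadata match all given field values."""
        out = []
        for i, m in enumerate(self.rows_meta):
            if all(getattr(m, k) == v for k, v in fields.items()):
                out.append(i)
        return np.asarray(out, dtype=int)

    def image(self, row: int) -> np.ndarray:
        return self.matrix[row].reshape(self.roi_shape)


def total_average_image(videos: Iterable[LabeledVideo]) -> np.ndarray:
    """Unweighted mean over the per-video mean-neutral images."""
    means = [mean_neutral_image(v) for v in videos]
    if not means:
        raise ValueError("no videos supplied")
    return np.mean(means, axis=0)


def select_optimal_neutral(
    video: LabeledVideo, override: Optional[int] = None
) -> int:
    """Index of the neutral frame closest (L2) to the video's mean neutral.

    A manual per-video override is honored when supplied.  Ties go to the
    smallest frame index.
    """
    idx = video.neutral_indices()
    if override is not None:
        if override not in idx:
            raise ValueError(
                f"override frame {override} is not a neutral frame of "
                f"{video.video_id}"
            )
        return int(override)
    if idx.size == 0:
        raise ValueError(f"video {video.video_id} has no neutral frames")
    mean = video.frames[idx].mean(axis=0)
    dists = [float(np.linalg.norm(video.frames[i] - mean)) for i in idx]
    return int(idx[int(np.argmin(dists))])  # argmin takes the first minimum


def crop_roi(frame: np.ndarray, roi: ROISpec) -> np.ndarray:
    """Exact sub-matrix copy of the ROI rectangle."""
    x0, y0, w, h = roi.rect
    fh, fw = frame.shape
    if x0 + w > fw or y0 + h > fh:
        raise ValueError(f"ROI {roi.rect} exceeds frame bounds {fw}x{fh}")
    return frame[y0 : y0 + h, x0 : x0 + w].copy()


def delta_image(
    frame_roi: np.ndarray,
    neutral_roi: np.ndarray,
    source: tuple[str, int] = ("", 0),
    region: Region = Region.UPPER,
) -> DeltaImage:
    """Element-wise signed difference frame_roi - neutral_roi."""
    frame_roi = np.asarray(frame_roi, dtype=float)
    neutral_roi = np.asarray(neutral_roi, dtype=float)
    if frame_roi.shape != neutral_roi.shape:
        raise ValueError(
            f"shape mismatch {frame_roi.shape} vs {neutral_roi.shape}"
        )
    return DeltaImage(frame_roi - neutral_roi, source, Region(region))


def build_database(
    videos: Sequence[LabeledVideo],
    roi: ROISpec,
    class_filter: Iterable[AUClass],
    neutral_overrides: Optional[Mapping[str, int]] = None,
) -> ImageDatabase:
    """Stack flattened delta-images of qualifying frames into a database.

    Videos must already be aligned.  Row order is deterministic: videos
    in the given order, frames in temporal order.
    """
    class_filter = set(class_filter)
    overrides = dict(neutral_overrides or {})
    rows: list[np.ndarray] = []
    meta: list[RowMeta] = []
    for video in videos:
        neutral_idx = select_optimal_neutral(
            video, overrides.get(video.video_id)
        )
        neutral_roi = crop_roi(video.frames[neutral_idx], roi)
        labels = video.labels(roi.region)
        for fi in range(video.n_frames):
            if labels[fi] not in class_filter:
                continue
            d = crop_roi(video.frames[fi], roi) - neutral_roi
            rows.append(d.ravel(order="C"))
            meta.append(
                RowMeta(video.video_id, fi, video.subject_id, labels[fi])
            )
    if not rows:
        raise ValueError("no frames match the class filter")
    return ImageDatabase(np.vstack(rows), meta, Region(roi.region), roi.shape)


def read_roi_config(path: str | Path) -> dict[Region, ROISpec]:
    """Read 'upper.rect'/'lower.rect' entries ("x0,y0,width,height")."""
    rois: dict[Region, ROISpec] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        key = key.strip()
        if key.endswith(".rect"):
            region = Region(key[: -len(".rect")])
            rect = tuple(int(v) for v in value.split(","))
            rois[region] = ROISpec(region, rect)  # type: ignore[arg-type]
    return rois


def write_roi_config(rois: Mapping[Region, ROISpec], path: str | Path) -> None:
    Path(path).write_text(
        "".join(
            f"{region.value}.rect: {','.join(map(str, roi.rect))}\n"
            for region, roi in rois.items()
        )
    )


def save_database(db: ImageDatabase, prefix: str | Path) -> None:
    """Write <prefix>.npy (matrix) and <prefix>.meta.csv (sidecar table)."""
    prefix = Path(prefix)
    np.save(prefix.with_suffix(".npy"), db.matrix)
    with prefix.with_suffix(".meta.csv").open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["row", "video_id", "frame_index", "subject_id", "class",
             "region", "roi_height", "roi_width"]
        )
        for i, m in enumerate(db.rows_meta):
            writer.writerow(
                [i, m.video_id, m.frame_index, m.subject_id,
                 m.au_class.value, db.region.value, *db.roi_shape]
            )


def load_database(prefix: str | Path) -> ImageDatabase:
    prefix = Path(prefix)
    matrix = np.load(prefix.with_suffix(".npy"))
    meta: list[RowMeta] = []
    region = Region.UPPER
    roi_shape = (0, 0)
    with prefix.with_suffix(".meta.csv").open(newline="") as fh:
        for row in csv.DictReader(fh):
            meta.append(
                RowMeta(
                    row["video_id"],
                    int(row["frame_index"]),
                    row["subject_id"],
                    AUClass(row["class"]),
                )
            )
            region = Region(row["region"])
            roi_shape = (int(row["roi_height"]), int(row["roi_width"]))
    return ImageDatabase(matrix, meta, region, roi_shape)
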