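"""File formats: label tables, landmark files, manifests, image sequences.

Label table (comma-delimited, header row)::

    video_id,frame_index,region,codes,intensity

with one row per coded frame per region; ``frame_index`` is 0-based,
``region`` is ``upper`` or ``lower``, ``codes`` joins raw AU codes with
"+" (empty for neutral), ``intensity`` is an optional letter.  Raw codes
themselves may contain "+" (e.g. ``AU1+2``), so the parser splits on "+"
and re-merges any token that does not start with ``AU``/``EAU`` into the
preceding token: ``AU1+2`` is one code, ``AU25+AU26`` is two.

Landmark file (comma-delimited, header row)::

    video_id,point_name,x,y

Manifest: ``key: value`` text lines with at least video_id, subject_id,
species and fps.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np

from .alignment import LANDMARK_NAMES, LandmarkSet
from .datamodel import FrameLabel, LabeledVideo, Region, to_grayscale

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


def _split_codes(text: str) -> frozenset[str]:
    if not text:
        return frozenset()
    tokens: list[str] = []
    for tok in text.split("+"):
        if tokens and not re.match(r"^E?AU", tok):
            tokens[-1] = tokens[-1] + "+" + tok
        else:
            tokens.append(tok)
    return frozenset(t for t in tokens if t)


def _join_codes(codes: Iterable[str]) -> str:
    return "+".join(sorted(codes))


def read_label_table(path: str | Path) -> list[FrameLabel]:
    """Parse a delimited label table into FrameLabel rows.

    Raises ValueError with the 1-based line number for an unknown region
    token or a negative frame index.
    """
    path = Path(path)
    labels: list[FrameLabel] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        for lineno, row in enumerate(reader, start=2):
            region = (row.get("region") or "").strip().lower()
            if region not in (Region.UPPER.value, Region.LOWER.value):
                raise ValueError(
                    f"{path}:{lineno}: unknown region {row.get('region')!r}"
                )
            try:
                frame_index = int(row["frame_index"])
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: bad frame_index") from exc
            if frame_index < 0:
                raise ValueError(f"{path}:{lineno}: negative frame index")
            labels.append(
                FrameLabel(
                    video_id=row["video_id"].strip(),
                    frame_index=frame_index,
                    region=Region(region),
                    raw_codes=_split_codes((row.get("codes") or "").strip()),
                    intensity=(row.get("intensity") or "").strip() or None,
                )
            )
    return labels


def write_label_table(labels: Sequence[FrameLabel], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["video_id", "frame_index", "region", "codes", "intensity"])
        for lab in labels:
            writer.writerow(
                [
                    lab.video_id,
                    lab.frame_index,
                    lab.region.value,
                    _join_codes(lab.raw_codes),
                    lab.intensity or "",
                ]
            )


def expand_events(
    events: Iterable[tuple[str, Region | str, Iterable[str], int, int]],
) -> list[FrameLabel]:
    """Expand (video_id, region, codes, start, stop) coding events to frames.

    Intervals are closed-open on frame indices, matching an event logger
    that records onset and offset times.
    """
    labels: list[FrameLabel] = []
    for video_id, region, codes, start, stop in events:
        for idx in range(int(start), int(stop)):
            labels.append(
                FrameLabel(video_id, idx, Region(region), frozenset(codes))
            )
    return labels


def read_manifest(path: str | Path) -> dict[str, str]:
    manifest: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        manifest[key.strip()] = value.strip()
    return manifest


def write_manifest(manifest: Mapping[str, object], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{k}: {v}\n" for k, v in manifest.items())
    )


def load_image_sequence(
    path: str | Path,
    manifest: Mapping[str, object] | str | Path,
    drop_codes: frozenset[str] = frozenset(),
) -> LabeledVideo:
    """Load a directory of frame images (lexicographic order) as a video.

    ``manifest`` is a mapping (or path to a manifest file) with video_id,
    subject_id, species and fps.  ``drop_codes`` is accepted here for API
    symmetry with label parsing but applied by the caller when attaching
    labels (see :func:`filter_labels`).
    """
    path = Path(path)
    if isinstance(manifest, (str, Path)):
        manifest = read_manifest(manifest)
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
    )
    if not files:
        raise FileNotFoundError(f"no frame images found under {path}")
    frames: list[np.ndarray] = []
    shape: tuple[int, int] | None = None
    for f in files:
        try:
            img = iio.imread(f)
        except Exception as exc:  # pragma: no cover - backend-specific
            raise IOError(f"cannot decode frame {f}") from exc
        gray = to_grayscale(np.asarray(img, dtype=float))
        if shape is None:
            shape = gray.shape
        elif gray.shape != shape:
            raise ValueError(
                f"frame {f.name} has shape {gray.shape}, expected {shape}"
            )
        frames.append(gray)
    return LabeledVideo(
        video_id=str(manifest["video_id"]),
        subject_id=str(manifest["subject_id"]),
        species=str(manifest.get("species", "synthetic")),
        frames=np.stack(frames),
        fps=float(manifest.get("fps", 30.0)),
    )


def filter_labels(
    labels: Sequence[FrameLabel], drop_codes: Iterable[str]
) -> list[FrameLabel]:
    """Drop raw codes globally (e.g. AU45 when its timing is unreliable)."""
    drop = frozenset(drop_codes)
    if not drop:
        return list(labels)
    out = []
    for lab in labels:
        out.append(
            FrameLabel(
                lab.video_id,
                lab.frame_index,
                lab.region,
                lab.raw_codes - drop,
                lab.intensity,
            )
        )
    return out


def read_landmarks(path: str | Path) -> dict[str, LandmarkSet]:
    """Read one landmark file (video_id, point_name, x, y) per dataset."""
    per_video: dict[str, dict[str, tuple[float, float]]] = {}
    with Path(path).open(newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            name = row["point_name"].strip()
            if name not in LANDMARK_NAMES:
                raise ValueError(f"{path}:{lineno}: unknown landmark {name!r}")
            per_video.setdefault(row["video_id"].strip(), {})[name] = (
                float(row["x"]),
                float(row["y"]),
            )
    return {vid: LandmarkSet(points) for vid, points in per_video.items()}


def write_landmarks(
    landmarks: Mapping[str, LandmarkSet], path: str | Path
) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["video_id", "point_name", "x", "y"])
        for vid in sorted(landmarks):
            for name in LANDMARK_NAMES:
                x, y = landmarks[vid].points[name]
                writer.writerow([vid, name, repr(float(x)), repr(float(y))])
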