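"""Shared fixtures: small synthetic datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from maqfacs.alignment import align_video
from maqfacs.datamodel import AUClass, Region, target_classes
from maqfacs.preprocess import build_database
from maqfacs.synthetic import (
    PoseJitter,
    SyntheticConfig,
    default_rois,
    generate_dataset,
)

ALL_MAGNITUDES = {
    AUClass.AU1_2: 10.0,
    AUClass.AU43_5: 10.0,
    AUClass.AU25_26: 10.0,
    AUClass.AU25_26_16: 10.0,
    AUClass.AU25_26_18I: 10.0,
}

#: balanced-ish frequencies used for desk-scale evaluation fixtures
EVAL_UPPER_FREQS = {
    AUClass.UPPER_NONE: 0.5,
    AUClass.AU43_5: 0.25,
    AUClass.AU1_2: 0.25,
}
EVAL_LOWER_FREQS = {
    AUClass.LOWER_NONE: 0.34,
    AUClass.AU25_26: 0.22,
    AUClass.AU25_26_18I: 0.22,
    AUClass.AU25_26_16: 0.22,
}


def small_config(**overrides) -> SyntheticConfig:
    kwargs = dict(
        image_size=(64, 56),
        n_subjects=3,
        videos_per_subject=2,
        frames_per_video=80,
        upper_frequencies=dict(EVAL_UPPER_FREQS),
        lower_frequencies=dict(EVAL_LOWER_FREQS),
        noise_sd=0.0,
        deformation_magnitudes=dict(ALL_MAGNITUDES),
        pose_jitter=PoseJitter(rotation_deg=5.0, scale=0.05, translation_px=3.0),
        seed=1234,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


@pytest.fixture(scope="session")
def small_dataset():
    config = small_config()
    dataset, ground_truth = generate_dataset(config)
    return config, dataset, ground_truth


@pytest.fixture(scope="session")
def aligned_videos(small_dataset):
    _, dataset, ground_truth = small_dataset
    return [align_video(v, ground_truth.landmarks[v.video_id]) for v in dataset]


@pytest.fixture(scope="session")
def upper_db(small_dataset, aligned_videos):
    config, _, _ = small_dataset
    roi = default_rois(config.image_size)[Region.UPPER]
    return build_database(
        aligned_videos, roi, set(target_classes(Region.UPPER))
    )


@pytest.fixture(scope="session")
def lower_db(small_dataset, aligned_videos):
    config, _, _ = small_dataset
    roi = default_rois(config.image_size)[Region.LOWER]
    return build_database(
        aligned_videos, roi, set(target_classes(Region.LOWER))
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20250925)
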