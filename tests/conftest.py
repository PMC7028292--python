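"""Shared synthetic fixtures.

All test inputs are generated programmatically from seeded scene specs, so
the suite needs no stored image data.
"""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import box

from orbitlite.pixel import (
    FeatureConfig,
    TrainingShape,
    assemble_training_set,
    train_pixel_classifier,
)
from orbitlite.synthetic import (
    BlobFieldSpec,
    SceneSpec,
    TextureRegionSpec,
    generate_scene,
)


@pytest.fixture(scope="session")
def blob_scene():
    """768x768 scene with exactly 37 bright blobs, 8 straddling the
    256-px tile grid."""
    spec = SceneSpec(
        width=768,
        height=768,
        seed=101,
        elements=[BlobFieldSpec(n=37, n_border=8, border_tile_size=256)],
    )
    return generate_scene(spec)


def two_region_spec(seed: int, split: float = 0.6, width: int = 640) -> SceneSpec:
    """Two texture regions of `split` / 1-split area with different mean
    intensity (separable classes)."""
    x = int(width * split)
    h = 640
    return SceneSpec(
        width=width,
        height=h,
        seed=seed,
        elements=[
            TextureRegionSpec(
                polygon=[(0, 0), (x, 0), (x, h), (0, h)],
                class_name="A", mean=0.35, amplitude=0.05, period=12,
                noise_sd=0.03,
            ),
            TextureRegionSpec(
                polygon=[(x, 0), (width, 0), (width, h), (x, h)],
                class_name="B", mean=0.65, amplitude=0.05, period=12,
                noise_sd=0.03,
            ),
        ],
    )


def frequency_pair_spec(seed: int, s1_period: float = 16.0,
                        s2_period: float = 96.0) -> SceneSpec:
    """Two gratings with equal mean and amplitude but different spatial
    period, plus pixel noise that drowns out 3x3-scale differences: only a
    classifier with enough context can tell them apart."""
    return SceneSpec(
        width=512,
        height=512,
        seed=seed,
        elements=[
            TextureRegionSpec(
                polygon=[(0, 0), (256, 0), (256, 512), (0, 512)],
                class_name="fine", mean=0.5, amplitude=0.25,
                period=s1_period, noise_sd=0.15,
            ),
            TextureRegionSpec(
                polygon=[(256, 0), (512, 0), (512, 512), (256, 512)],
                class_name="coarse", mean=0.5, amplitude=0.25,
                period=s2_period, noise_sd=0.15,
            ),
        ],
    )


@pytest.fixture(scope="session")
def texture_scene():
    return generate_scene(two_region_spec(seed=202))


@pytest.fixture(scope="session")
def texture_model(texture_scene):
    """Pixel classifier separating the two texture regions."""
    img, _ = texture_scene
    cfg = FeatureConfig(structure_size=4)
    shapes = [
        TrainingShape("A", box(20, 20, 140, 140)),
        TrainingShape("B", box(420, 20, 540, 140)),
    ]
    X, y, names = assemble_training_set(shapes, [img], cfg, seed=0)
    return train_pixel_classifier(X, y, names, cfg, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
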