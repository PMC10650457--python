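"""Synthetic offline test data.

Two generators:

* :func:`make_image_dataset` — small labeled image sets whose classes
  differ in texture period (fine vs coarse stripes) and in the placement
  of a bright ellipse, so the classes are distinguishable at more than one
  spatial scale and pyramid features are genuinely informative.  Images
  are written as 8-bit PNGs in a directory-per-class layout that
  :func:`pyrafex.features.build_feature_table` consumes directly.

* :func:`make_feature_table` — labeled feature tables where a known subset
  of columns is shifted between two balanced classes by a stated effect
  size (in sd units) and every other column is pure standard-normal noise.
  The planted indices are the ground truth for feature-selection tests.

Everything is reproducible bit-exactly from (spec, seed).  These fixtures
emulate class structure, not radiograph anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import FeatureTable

__all__ = ["ImageFixtureSpec", "TableFixtureSpec", "make_image_dataset",
           "make_feature_table", "render_class_image"]


@dataclass(frozen=True)
class ImageFixtureSpec:
    n_classes: int = 2
    images_per_class: int = 10
    side: int = 224
    texture_scales: tuple[int, ...] = (8, 64)  # stripe periods in px
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.side < max(self.texture_scales):
            raise ValueError("side must be >= max texture scale")


@dataclass(frozen=True)
class TableFixtureSpec:
    n_samples: int = 200
    n_features: int = 50
    informative_indices: tuple[int, ...] = (0, 1, 2, 3, 4)
    effect_size: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 <= i < self.n_features for i in self.informative_indices):
            raise ValueError("informative_indices out of range")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")


def render_class_image(
    spec: ImageFixtureSpec, class_index: int, image_index: int
) -> np.ndarray:
    """Deterministic class pattern + seeded Gaussian noise, in [0, 1].

    The class picks a stripe period from ``texture_scales`` (fine periods
    separate classes at small patch scales, coarse at large ones), a
    stripe orientation, and an ellipse center/size, so both texture and
    shape carry the label.
    """
    period = spec.texture_scales[class_index % len(spec.texture_scales)]
    horizontal = (class_index // len(spec.texture_scales)) % 2 == 0
    yy, xx = np.mgrid[0 : spec.side, 0 : spec.side].astype(np.float64)
    coord = yy if horizontal else xx
    img = 0.5 + 0.25 * np.sin(2 * np.pi * coord / period)

    # class-specific bright ellipse: center walks around the image center
    angle = 2 * np.pi * class_index / spec.n_classes
    cy = spec.side * (0.5 + 0.25 * np.sin(angle))
    cx = spec.side * (0.5 + 0.25 * np.cos(angle))
    ry = spec.side * 0.12
    rx = spec.side * (0.08 + 0.02 * (class_index % 3))
    mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    img = np.where(mask, np.clip(img + 0.3, 0, 1), img)

    rng = np.random.default_rng([spec.seed, class_index, image_index])
    img = img + spec.noise_sd * rng.standard_normal(img.shape)
    return np.clip(img, 0.0, 1.0)


def make_image_dataset(spec: ImageFixtureSpec, out_dir: str | Path) -> Path:
    """Write the labeled PNG dataset; returns the dataset root.

    Layout: ``out_dir/class_<c>/img_<i>.png``.  Rerunning with the same
    spec produces byte-identical files.
    """
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for c in range(spec.n_classes):
        class_dir = out_dir / f"class_{c}"
        class_dir.mkdir(exist_ok=True)
        for i in range(spec.images_per_class):
            img = render_class_image(spec, c, i)
            arr8 = np.round(img * 255).astype(np.uint8)
            Image.fromarray(arr8, mode="L").save(
                class_dir / f"img_{i:03d}.png", optimize=False
            )
    return out_dir


def make_feature_table(spec: TableFixtureSpec) -> FeatureTable:
    """Two balanced classes; planted columns shifted by ``effect_size`` sd.

    Noise columns are iid standard normal for every sample; each planted
    column gains ``effect_size`` for class "b" samples only, so its
    between-class mean gap is exactly the effect size in noise-sd units.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_samples, spec.n_features
    mat = rng.standard_normal((n, d))
    half = n // 2
    labels = np.array(["a"] * half + ["b"] * (n - half))
    for idx in spec.informative_indices:
        mat[half:, idx] += spec.effect_size
    ids = [f"s{i:04d}" for i in range(n)]
    cols = [f"f{i:06d}" for i in range(d)]
    return FeatureTable(mat, labels, ids, cols)
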