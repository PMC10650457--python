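"""Per-image pyramid feature vectors and per-dataset feature tables.

Each pyramid view is pushed through the backbone independently and the
resulting blocks are concatenated in the fixed view order, giving one long
exemplar vector per image (85 x 1000 = 85,000 columns with the defaults).
A dataset directory whose immediate subdirectories are class labels becomes
a FeatureTable: one row per image, labels from directory names, row order
sorted by path so repeated runs are bit-identical.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .backbones import FeatureExtractor
from .pyramid import PatchAddress, PyramidConfig, load_image, pyramid_views

__all__ = [
    "FeatureVector",
    "FeatureTable",
    "extract_pyramid_features",
    "build_feature_table",
    "column_names",
    "save_table_csv",
    "load_table_csv",
]

log = logging.getLogger(__name__)

IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class FeatureVector:
    """One image's concatenated pyramid features with block provenance."""

    values: np.ndarray
    provenance: tuple[tuple[PatchAddress, int], ...]  # (address, column offset)


@dataclass
class FeatureTable:
    """N samples x D features with labels, sample ids and stable column order."""

    matrix: np.ndarray
    labels: np.ndarray
    sample_ids: list[str]
    column_names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        n, d = self.matrix.shape
        if len(self.labels) != n or len(self.sample_ids) != n:
            raise ValueError("labels/sample_ids length must match row count")
        if len(self.column_names) != d:
            raise ValueError("column_names length must match column count")
        if not np.isfinite(self.matrix).all():
            raise ValueError("feature table contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def subset_columns(self, indices: np.ndarray | list[int]) -> "FeatureTable":
        idx = np.asarray(indices, dtype=np.intp)
        return FeatureTable(
            self.matrix[:, idx],
            self.labels.copy(),
            list(self.sample_ids),
            [self.column_names[i] for i in idx],
        )


def column_names(config: PyramidConfig, backbone: FeatureExtractor) -> list[str]:
    """Stable column names encoding scale/row/col and within-block index."""
    from .pyramid import resize_to_working, tile  # addresses only

    names: list[str] = []
    for side in config.patch_sides:
        n = config.working_side // side
        for r in range(n):
            for c in range(n):
                names.extend(
                    f"s{side}_r{r}_c{c}_{i:04d}" for i in range(backbone.output_dim)
                )
    if config.include_full_image:
        names.extend(
            f"s{config.working_side}_r0_c0_{i:04d}"
            for i in range(backbone.output_dim)
        )
    return names


def extract_pyramid_features(
    image: np.ndarray, backbone: FeatureExtractor, config: PyramidConfig
) -> FeatureVector:
    """Concatenate backbone features over all pyramid views of one image.

    Block b of the output is ``backbone(view_b)`` with views in
    :func:`pyrafex.pyramid.pyramid_views` order, so the vector length is
    (number of views) x ``backbone.output_dim``.
    """
    blocks: list[np.ndarray] = []
    prov: list[tuple[PatchAddress, int]] = []
    offset = 0
    for addr, view in pyramid_views(image, config):
        blocks.append(backbone(view))
        prov.append((addr, offset))
        offset += backbone.output_dim
    return FeatureVector(np.concatenate(blocks), tuple(prov))


def _iter_dataset(dataset_dir: Path) -> list[tuple[str, Path]]:
    """(label, image path) pairs, sorted by class then filename."""
    pairs: list[tuple[str, Path]] = []
    for class_dir in sorted(p for p in dataset_dir.iterdir() if p.is_dir()):
        for img in sorted(class_dir.iterdir()):
            if img.suffix.lower() in IMAGE_SUFFIXES:
                pairs.append((class_dir.name, img))
    return pairs


def build_feature_table(
    dataset_dir: str | Path,
    backbone: FeatureExtractor,
    config: PyramidConfig | None = None,
) -> FeatureTable:
    """Extract pyramid features for every image under a labeled directory.

    The directory's immediate subdirectories are the class labels.  Rows
    are ordered by (class, filename) so reruns are deterministic.
    Unreadable images are skipped with a warning; an empty dataset raises.
    """
    config = config or PyramidConfig()
    dataset_dir = Path(dataset_dir)
    if not dataset_dir.is_dir():
        raise FileNotFoundError(f"dataset directory not found: {dataset_dir}")
    pairs = _iter_dataset(dataset_dir)
    if not pairs:
        raise ValueError(f"no labeled images found under {dataset_dir}")

    rows, labels, ids = [], [], []
    skipped = 0
    for label, path in pairs:
        try:
            img = load_image(path)
        except Exception as exc:  # unreadable file: skip, keep going
            skipped += 1
            warnings.warn(f"skipping unreadable image {path}: {exc}")
            continue
        rows.append(extract_pyramid_features(img, backbone, config).values)
        labels.append(label)
        ids.append(str(path.relative_to(dataset_dir)))
    if not rows:
        raise ValueError(f"all {skipped} images under {dataset_dir} were unreadable")

    counts = pd.Series(labels).value_counts().sort_index()
    log.info(
        "built feature table: %d rows, %d skipped, per-class counts %s",
        len(rows), skipped, counts.to_dict(),
    )
    return FeatureTable(
        np.vstack(rows), np.asarray(labels), ids, column_names(config, backbone)
    )


def save_table_csv(table: FeatureTable, path: str | Path) -> None:
    """Write a table as CSV: columns ``sample_id,label,<feature columns>``."""
    df = pd.DataFrame(table.matrix, columns=table.column_names)
    df.insert(0, "label", table.labels)
    df.insert(0, "sample_id", table.sample_ids)
    df.to_csv(path, index=False, float_format="%.17g")


def load_table_csv(path: str | Path) -> FeatureTable:
    """Read a table written by :func:`save_table_csv`."""
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns[:2]) != ["sample_id", "label"]:
        raise ValueError("expected leading columns sample_id,label")
    return FeatureTable(
        df.iloc[:, 2:].to_numpy(dtype=np.float64),
        df["label"].to_numpy(),
        df["sample_id"].astype(str).tolist(),
        list(df.columns[2:]),
    )
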