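"""Feature backbones: the image -> fixed-length vector contract.

A backbone is any callable object mapping a working-resolution RGB image to
a finite real vector of fixed length (default 1000, modeled on the final
1000-unit fully-connected layer of an ImageNet-pretrained convolutional
network).  The pipeline is weight-agnostic: it only relies on the contract,
so a deterministic offline stub and an optional adapter for a torchvision
pretrained network are interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .pyramid import as_rgb_image

__all__ = ["FeatureExtractor", "stub_backbone", "pretrained_backbone_adapter",
           "BackboneUnavailableError"]


class BackboneUnavailableError(RuntimeError):
    """A requested pretrained backbone cannot be loaded in this environment."""


@dataclass(frozen=True)
class FeatureExtractor:
    """A named, deterministic image -> feature-vector mapping.

    ``fn`` must be pure: the same image always yields the same vector, and
    every output is finite with length ``output_dim``.
    """

    name: str
    output_dim: int
    fn: Callable[[np.ndarray], np.ndarray]

    def __call__(self, image: np.ndarray) -> np.ndarray:
        vec = np.asarray(self.fn(as_rgb_image(image)), dtype=np.float64)
        if vec.shape != (self.output_dim,):
            raise ValueError(
                f"backbone {self.name!r} returned shape {vec.shape}, "
                f"expected ({self.output_dim},)"
            )
        if not np.isfinite(vec).all():
            raise ValueError(f"backbone {self.name!r} returned non-finite values")
        return vec


_POOL_GRID = 14  # stub pools each view to a 14x14 grayscale grid


def stub_backbone(seed: int = 0, output_dim: int = 1000) -> FeatureExtractor:
    """Deterministic, content-sensitive stand-alone backbone.

    The view is converted to grayscale, mean-pooled onto a fixed 14x14
    grid, flattened, passed through a seeded random Gaussian linear
    projection to ``output_dim``, and squashed with tanh.  Distinct image
    content generally yields distinct vectors; the same (seed, image) pair
    always yields the same vector.
    """
    if output_dim < 1:
        raise ValueError("output_dim must be >= 1")
    rng = np.random.default_rng(seed)
    in_dim = _POOL_GRID * _POOL_GRID
    # fixed projection drawn once at construction
    weight = rng.standard_normal((output_dim, in_dim)) / np.sqrt(in_dim)
    bias = rng.standard_normal(output_dim) * 0.1

    def _features(image: np.ndarray) -> np.ndarray:
        gray = image.mean(axis=2)
        h, w = gray.shape
        if h % _POOL_GRID == 0 and w % _POOL_GRID == 0:
            pooled = gray.reshape(
                _POOL_GRID, h // _POOL_GRID, _POOL_GRID, w // _POOL_GRID
            ).mean(axis=(1, 3))
        else:
            # mean-pool via box membership of pixel rows/cols
            row_bins = np.minimum((np.arange(h) * _POOL_GRID) // h, _POOL_GRID - 1)
            col_bins = np.minimum((np.arange(w) * _POOL_GRID) // w, _POOL_GRID - 1)
            sums = np.zeros((_POOL_GRID, _POOL_GRID))
            counts = np.zeros((_POOL_GRID, _POOL_GRID))
            np.add.at(sums, (row_bins[:, None], col_bins[None, :]), gray)
            np.add.at(counts, (row_bins[:, None], col_bins[None, :]),
                      np.ones_like(gray))
            pooled = sums / np.maximum(counts, 1.0)
        return np.tanh(weight @ pooled.ravel() + bias)

    return FeatureExtractor(f"stub(seed={seed})", output_dim, _features)


def pretrained_backbone_adapter(
    model_id: str = "efficientnet_b0", layer: str = "classifier"
) -> FeatureExtractor:
    """Wrap a locally available torchvision pretrained network.

    Exposes the activations of ``layer`` (default: the final 1000-unit
    fully-connected classifier head) as the feature vector, applying the
    network's own preprocessing internally and running in eval mode so
    repeated calls are identical.

    Raises
    ------
    BackboneUnavailableError
        If torch/torchvision or the pretrained weights are not available;
        the message points to :func:`stub_backbone` as the offline
        alternative.
    """
    try:
        import torch
        from torchvision import models, transforms
    except ImportError as exc:
        raise BackboneUnavailableError(
            "torch/torchvision are not installed; use stub_backbone() for a "
            "fully offline deterministic feature extractor"
        ) from exc

    try:
        model = models.get_model(model_id, weights="DEFAULT")
    except Exception as exc:  # missing weights, unknown model, no network
        raise BackboneUnavailableError(
            f"pretrained weights for {model_id!r} could not be loaded "
            "(offline?); use stub_backbone() instead"
        ) from exc
    model.eval()

    if layer != "classifier":
        # tap an intermediate module by dotted name
        from torchvision.models.feature_extraction import create_feature_extractor

        model = create_feature_extractor(model, return_nodes={layer: "out"})

    prep = transforms.Compose(
        [
            transforms.ToTensor(),
            transforms.Normalize(
                mean=[0.485, 0.456, 0.406], std=[0.229, 0.224, 0.225]
            ),
        ]
    )

    with torch.no_grad():
        probe = torch.zeros(1, 3, 224, 224)
        out = model(probe)
        if isinstance(out, dict):
            out = out["out"]
        output_dim = int(out.reshape(1, -1).shape[1])

    def _features(image: np.ndarray) -> np.ndarray:
        with torch.no_grad():
            x = prep((image * 255).astype(np.uint8)).unsqueeze(0)
            out = model(x)
            if isinstance(out, dict):
                out = out["out"]
            return out.reshape(-1).numpy().astype(np.float64)

    return FeatureExtractor(f"{model_id}:{layer}", output_dim, _features)
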