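"""Exemplar-pyramid geometry: resize, non-overlapping tiling, patch upscaling.

A radiograph is first stretched (plain bilinear, aspect ratio not preserved)
to a square working resolution (default 224 px).  It is then tiled into
non-overlapping grids of 28-, 56- and 112-px patches, and each patch is
bilinearly upscaled back to the working resolution so that every "view"
presented to the feature backbone has identical shape.  With the defaults
this yields 64 + 16 + 4 + 1 = 85 views per image.

All images are H x W x 3 float arrays with intensities in [0, 1]; grayscale
sources are channel-replicated on load so three channels always exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PyramidConfig",
    "PatchAddress",
    "as_rgb_image",
    "load_image",
    "bilinear_resize",
    "resize_to_working",
    "tile",
    "upscale_patch",
    "pyramid_views",
    "n_views",
]


class InvalidImageError(ValueError):
    """Raised for empty or non-finite image input."""


class ConfigurationError(ValueError):
    """Raised for a pyramid configuration the geometry cannot satisfy."""


@dataclass(frozen=True)
class PyramidConfig:
    """Geometry of the exemplar pyramid.

    Parameters
    ----------
    working_side:
        Side of the square working resolution every view is presented at.
    patch_sides:
        Strictly increasing patch sides; each must divide ``working_side``
        exactly so patches tile the image without overlap or remainder.
    include_full_image:
        Whether the un-tiled working-resolution image is appended as the
        final view.
    interpolation:
        Only ``"bilinear"`` is supported (half-pixel centers, edge clamp,
        no antialiasing).
    """

    working_side: int = 224
    patch_sides: tuple[int, ...] = (28, 56, 112)
    include_full_image: bool = True
    interpolation: str = "bilinear"

    def __post_init__(self) -> None:
        if self.working_side <= 0:
            raise ConfigurationError("working_side must be positive")
        if self.interpolation != "bilinear":
            raise ConfigurationError(
                f"unsupported interpolation {self.interpolation!r}"
            )
        sides = tuple(int(s) for s in self.patch_sides)
        object.__setattr__(self, "patch_sides", sides)
        if list(sides) != sorted(set(sides)):
            raise ConfigurationError("patch_sides must be strictly increasing")
        for s in sides:
            if s <= 0 or self.working_side % s:
                raise ConfigurationError(
                    f"patch side {s} does not divide working_side "
                    f"{self.working_side}"
                )


@dataclass(frozen=True)
class PatchAddress:
    """Grid position of one view: scale side and 0-based row/column.

    The full-image view is addressed as ``scale_side == working_side`` at
    row 0, column 0.
    """

    scale_side: int
    row_index: int
    col_index: int


def as_rgb_image(pixels: np.ndarray) -> np.ndarray:
    """Coerce an array to H x W x 3 float64 in [0, 1].

    2-D (grayscale) input is channel-replicated.  Raises
    :class:`InvalidImageError` on empty or non-finite input and on
    intensities outside [0, 1].
    """
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.size == 0:
        raise InvalidImageError("empty image")
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidImageError(f"expected HxW or HxWx3 array, got {arr.shape}")
    if not np.isfinite(arr).all():
        raise InvalidImageError("image contains non-finite intensities")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise InvalidImageError("intensities must lie in [0, 1]")
    return arr


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG file into an RGB image in [0, 1].

    8-bit intensities are divided by 255; 16-bit by 65535.  Alpha channels
    are dropped; grayscale is channel-replicated.
    """
    from PIL import Image

    with Image.open(path) as im:
        im = im.convert("RGB")
        arr = np.asarray(im, dtype=np.float64) / 255.0
    return as_rgb_image(arr)


def bilinear_resize(image: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resample with half-pixel sample centers and edge clamping.

    Output pixel (i, j) samples the input at
    ``((i + 0.5) * H_in / H_out - 0.5, (j + 0.5) * W_in / W_out - 0.5)``,
    the align-corners-disabled convention, with coordinates clamped to the
    valid range (edge replication).  No antialiasing prefilter is applied.
    Being a convex combination of input pixels, the output stays in [0, 1].
    """
    img = np.asarray(image, dtype=np.float64)
    in_h, in_w = img.shape[:2]
    if (in_h, in_w) == (out_h, out_w):
        return img.copy()

    def _axis_coords(n_in: int, n_out: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        centers = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
        centers = np.clip(centers, 0.0, n_in - 1.0)
        lo = np.floor(centers).astype(np.intp)
        hi = np.minimum(lo + 1, n_in - 1)
        frac = centers - lo
        return lo, hi, frac

    r0, r1, rf = _axis_coords(in_h, out_h)
    c0, c1, cf = _axis_coords(in_w, out_w)
    rf = rf[:, None, None]
    cf = cf[None, :, None]
    top = img[r0][:, c0] * (1 - cf) + img[r0][:, c1] * cf
    bot = img[r1][:, c0] * (1 - cf) + img[r1][:, c1] * cf
    return top * (1 - rf) + bot * rf


def resize_to_working(image: np.ndarray, config: PyramidConfig) -> np.ndarray:
    """Stretch an image to ``working_side`` square (bit-identical if already there)."""
    img = as_rgb_image(image)
    s = config.working_side
    if img.shape[0] == s and img.shape[1] == s:
        return img
    return bilinear_resize(img, s, s)


def tile(
    image: np.ndarray, scale_side: int, working_side: int | None = None
) -> list[tuple[PatchAddress, np.ndarray]]:
    """Cut a working-resolution image into a row-major grid of patches.

    Pixel values are copied, never interpolated; the patches are disjoint
    and jointly cover the image exactly.
    """
    img = as_rgb_image(image)
    side = img.shape[0]
    if working_side is not None and side != working_side:
        raise ConfigurationError(
            f"image side {side} differs from working_side {working_side}"
        )
    if img.shape[1] != side:
        raise ConfigurationError("tile expects a square image")
    if scale_side <= 0 or side % scale_side:
        raise ConfigurationError(
            f"scale_side {scale_side} does not divide image side {side}"
        )
    n = side // scale_side
    out: list[tuple[PatchAddress, np.ndarray]] = []
    for r in range(n):
        for c in range(n):
            patch = img[
                r * scale_side : (r + 1) * scale_side,
                c * scale_side : (c + 1) * scale_side,
            ].copy()
            out.append((PatchAddress(scale_side, r, c), patch))
    return out


def upscale_patch(patch: np.ndarray, config: PyramidConfig) -> np.ndarray:
    """Bilinearly upscale a patch back to the working resolution."""
    p = as_rgb_image(patch)
    s = config.working_side
    if p.shape[0] > s or p.shape[1] > s:
        raise ConfigurationError("patch larger than working resolution")
    if p.shape[0] == s and p.shape[1] == s:
        return p
    return bilinear_resize(p, s, s)


def pyramid_views(
    image: np.ndarray, config: PyramidConfig
) -> list[tuple[PatchAddress, np.ndarray]]:
    """All pyramid views of one image, each at working resolution.

    Order is fixed and reproducible: smallest patch scale first, patches
    row-major within a scale, then the next scale, and (if configured) the
    full working-resolution image last.  With the defaults the list holds
    64 + 16 + 4 + 1 = 85 views.
    """
    working = resize_to_working(image, config)
    views: list[tuple[PatchAddress, np.ndarray]] = []
    for side in config.patch_sides:
        for addr, patch in tile(working, side, config.working_side):
            views.append((addr, upscale_patch(patch, config)))
    if config.include_full_image:
        views.append(
            (PatchAddress(config.working_side, 0, 0), working)
        )
    return views


def n_views(config: PyramidConfig) -> int:
    """Number of views the pyramid produces per image."""
    total = sum((config.working_side // s) ** 2 for s in config.patch_sides)
    return total + (1 if config.include_full_image else 0)
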