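"""Core in-memory containers for single-channel images and feature maps.

Intensities live on the unit interval; ``levels`` records the gray-level
count of the originating format so histogram-based metrics (entropy, mutual
information) can quantize consistently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = ["SourceTag", "Image", "FeatureMap", "as_pixels"]


class SourceTag(str, Enum):
    """Which modality (or processing stage) an image came from."""

    CT = "CT"
    MR = "MR"
    FUSED = "FUSED"
    OTHER = "OTHER"


@dataclass
class Image:
    """A single-channel 2-D image with intensities in [0, 1].

    Parameters
    ----------
    pixels
        H x W float array, all values finite and inside [0, 1].
    levels
        Gray-level count of the source format (256 for 8-bit input);
        used by histogram metrics.
    source_tag
        Modality label, one of :class:`SourceTag`.
    """

    pixels: np.ndarray
    levels: int = 256
    source_tag: SourceTag = SourceTag.OTHER

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D array, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite pixels")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("image intensities must lie in [0, 1]")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        self.source_tag = SourceTag(self.source_tag)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def require_min_size(self, minimum: int) -> None:
        h, w = self.pixels.shape
        if h < minimum or w < minimum:
            raise ValueError(
                f"image of size {h}x{w} is below the required minimum {minimum}x{minimum}"
            )


@dataclass
class FeatureMap:
    """A C x H x W stack of network activations.

    ``stage`` names the layer that produced it, e.g. ``"res2net_block"``.
    """

    values: np.ndarray
    stage: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected C x H x W, got shape {self.values.shape}")

    @property
    def channels(self) -> int:
        return self.values.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.values.shape[1:]  # type: ignore[return-value]


def as_pixels(img, min_size: int = 2) -> np.ndarray:
    """Coerce an :class:`Image` or bare 2-D array to a float64 pixel array.

    Metric functions accept both; the network boundary constructs a full
    :class:`Image` and enforces its stricter minimum size itself.
    """
    arr = img.pixels if isinstance(img, Image) else np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    if arr.shape[0] < min_size or arr.shape[1] < min_size:
        raise ValueError(f"image must be at least {min_size}x{min_size}, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite pixels")
    return arr.astype(np.float64, copy=False)
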