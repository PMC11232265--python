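"""Parameter-free fusion strategies for extracted feature maps.

The spatial-mean-attention strategy computes, for every source image i and
pixel (x, y), the channel-wise mean Q_i(x, y) of its feature stack, then
normalizes across sources::

    w_i(x, y) = Q_i(x, y) / (sum_j Q_j(x, y) + eps)

and fuses by the per-pixel convex combination f(c, x, y) = sum_i w_i(x, y)
phi_i(c, x, y).  Features arrive post-ReLU so Q_i >= 0; pixels where every
source is exactly zero fall back to uniform weights 1/s.  ``addition`` and
``average`` baselines are kept for comparison runs.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import uniform_filter

from .image import FeatureMap

__all__ = [
    "WeightMap",
    "compute_weight_maps",
    "fuse_features",
    "fuse",
    "STRATEGIES",
]


class WeightMap:
    """Per-source H x W fusion weights; entries in [0, 1], summing to 1 per pixel."""

    def __init__(self, weights: np.ndarray):
        weights = np.asarray(weights, dtype=np.float64)
        if weights.ndim != 3 or weights.shape[0] < 2:
            raise ValueError(f"expected s x H x W with s >= 2, got {weights.shape}")
        self.weights = weights

    @property
    def n_sources(self) -> int:
        return self.weights.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.weights.shape[1:]


def _stack(features) -> np.ndarray:
    arrays = [np.asarray(f.values if isinstance(f, FeatureMap) else f, dtype=np.float64)
              for f in features]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"feature maps must share C, H, W; got shapes {sorted(shapes)}")
    if arrays[0].ndim != 3:
        raise ValueError("each feature map must be C x H x W")
    return np.stack(arrays)  # (s, C, H, W)


def compute_weight_maps(features, epsilon: float = 1e-8, weight_mode: str = "l1",
                        local_window: int | None = None) -> WeightMap:
    """Spatial-mean-attention weight maps from >= 2 source feature stacks.

    ``weight_mode="l1"`` is the plain normalized-mean rule; ``"softmax"``
    exponentiates the channel means before normalizing.  ``local_window``
    (odd int) additionally box-filters the channel means, a reading of the
    "local average" variant; default off.
    """
    stack = _stack(features)
    if stack.shape[0] < 2:
        raise ValueError("need at least two sources to fuse")
    if stack.min() < 0:
        warnings.warn(
            "feature values below zero violate the post-ReLU contract; "
            "clamping at zero for weight computation",
            RuntimeWarning,
            stacklevel=2,
        )
        stack = np.clip(stack, 0.0, None)
    q = stack.mean(axis=1)  # (s, H, W) channel-wise means
    if local_window is not None:
        if local_window % 2 == 0 or local_window < 1:
            raise ValueError("local_window must be a positive odd integer")
        q = np.stack([uniform_filter(qi, size=local_window, mode="nearest") for qi in q])
    if weight_mode == "softmax":
        q = np.exp(q - q.max(axis=0, keepdims=True))
    elif weight_mode != "l1":
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    total = q.sum(axis=0)
    s = stack.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        w = q / (total[None] + epsilon)
    w[:, total == 0.0] = 1.0 / s
    return WeightMap(w)


def fuse_features(features, w: WeightMap) -> FeatureMap:
    """Weighted per-pixel sum of the source feature stacks (broadcast over C)."""
    stack = _stack(features)
    weights = w.weights if isinstance(w, WeightMap) else np.asarray(w, dtype=np.float64)
    if weights.shape[0] != stack.shape[0] or weights.shape[1:] != stack.shape[2:]:
        raise ValueError(
            f"weight maps {weights.shape} inconsistent with features "
            f"{(stack.shape[0],) + stack.shape[2:]}"
        )
    fused = np.einsum("sxy,scxy->cxy", weights, stack)
    return FeatureMap(fused, stage="fusion")


def _fuse_mean_attention(features, **kwargs) -> FeatureMap:
    return fuse_features(features, compute_weight_maps(features, **kwargs))


def _fuse_addition(features, **kwargs) -> FeatureMap:
    return FeatureMap(_stack(features).sum(axis=0), stage="fusion")


def _fuse_average(features, **kwargs) -> FeatureMap:
    return FeatureMap(_stack(features).mean(axis=0), stage="fusion")


STRATEGIES = {
    "mean_attention": _fuse_mean_attention,
    "addition": _fuse_addition,
    "average": _fuse_average,
}


def fuse(features, strategy: str = "mean_attention", **kwargs) -> FeatureMap:
    """Fuse source feature stacks with a named strategy from the registry."""
    try:
        fn = STRATEGIES[strategy]
    except KeyError:
        raise ValueError(
            f"unknown strategy {strategy!r}; available: {sorted(STRATEGIES)}"
        ) from None
    return fn(features, **kwargs)
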