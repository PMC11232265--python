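"""Feature extractor, Res2Net block, and feature reconstructor.

The extractor is two 3x3 convolutions (1->32, 32->64, ReLU) followed by a
scale-4 Res2Net block operating at 64 channels.  The block squeezes through
a 1x1 convolution, splits the result channel-wise into four ordered groups
of 16, chains the groups through 3x3 convolutions with inter-group residual
additions::

    y1 = x1
    y2 = H2(x2)
    y_i = H_i(x_i + y_{i-1})   for i in {3, 4}

concatenates the y_i back to 64 channels and expands through a closing 1x1
convolution.  The reconstructor is four 3x3 convolutions
(64->64->32->16->1); the final layer carries no activation and its output
is clamped to [0, 1] at inference.

All convolutions are stride 1 with zero padding, so every stage preserves
the spatial size — a requirement of the per-position fusion weights.
Forward passes optionally record caches so the training loop can run the
hand-written backward pass in :func:`autoencoder_backward`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .image import FeatureMap, Image, SourceTag
from .nn import conv2d_backward, conv2d_forward, relu_backward, relu_forward

__all__ = [
    "LayerSpec",
    "NetworkParams",
    "layer_inventory",
    "init_params",
    "res2net_block",
    "extract_features",
    "reconstruct",
    "autoencoder_forward",
    "autoencoder_backward",
    "save_checkpoint",
    "load_checkpoint",
]

FUSION_CHANNELS = 64  # channel count at the extractor/fusion interface
N_GROUPS = 4          # Res2Net scale
MIN_IMAGE_SIZE = 8


@dataclass(frozen=True)
class LayerSpec:
    """One convolution layer: kernel size, channel fan, activation."""

    name: str
    kernel_size: int
    in_channels: int
    out_channels: int
    activation: str  # "relu" | "none"
    stride: int = 1

    def __post_init__(self):
        if self.stride != 1:
            raise ValueError("all layers are stride 1")
        if self.activation not in ("relu", "none"):
            raise ValueError(f"unknown activation {self.activation!r}")


def layer_inventory(group_conv_depth: int = 1, channels: int = FUSION_CHANNELS) -> list[LayerSpec]:
    """Full layer list of extractor + Res2Net block + reconstructor.

    ``group_conv_depth`` selects one (default) or two stacked 3x3
    convolutions per Res2Net group; ``channels`` is the block width (64 for
    the real network, smaller multiples of 4 for toy oracles).
    """
    if channels % N_GROUPS != 0:
        raise ValueError(f"block width must be divisible by {N_GROUPS}")
    g = channels // N_GROUPS
    layers = [
        LayerSpec("enc_conv1", 3, 1, 32, "relu"),
        LayerSpec("enc_conv2", 3, 32, channels, "relu"),
        LayerSpec("block_squeeze", 1, channels, channels, "relu"),
    ]
    for i in range(2, N_GROUPS + 1):
        for d in range(group_conv_depth):
            suffix = f"block_h{i}" if group_conv_depth == 1 else f"block_h{i}_{d + 1}"
            layers.append(LayerSpec(suffix, 3, g, g, "relu"))
    layers += [
        LayerSpec("block_expand", 1, channels, channels, "relu"),
        LayerSpec("dec_conv1", 3, channels, 64, "relu"),
        LayerSpec("dec_conv2", 3, 64, 32, "relu"),
        LayerSpec("dec_conv3", 3, 32, 16, "relu"),
        LayerSpec("dec_conv4", 3, 16, 1, "none"),
    ]
    return layers


@dataclass
class NetworkParams:
    """All kernels and biases of the network, keyed by layer name."""

    weights: dict  # name -> np.ndarray (C_out, C_in, k, k)
    biases: dict   # name -> np.ndarray (C_out,)
    seed: int
    group_conv_depth: int = 1
    channels: int = FUSION_CHANNELS

    @property
    def inventory(self) -> list[LayerSpec]:
        return layer_inventory(self.group_conv_depth, self.channels)

    def n_parameters(self) -> int:
        return sum(w.size for w in self.weights.values()) + sum(
            b.size for b in self.biases.values()
        )

    def trainable(self) -> dict:
        """Flat name -> array view used by the optimizer (in-place updates)."""
        flat = {f"{n}.weight": w for n, w in self.weights.items()}
        flat.update({f"{n}.bias": b for n, b in self.biases.items()})
        return flat

    def config_hash(self) -> str:
        meta = {
            "seed": self.seed,
            "group_conv_depth": self.group_conv_depth,
            "channels": self.channels,
            "layers": [(s.name, s.kernel_size, s.in_channels, s.out_channels, s.activation)
                       for s in self.inventory],
        }
        return hashlib.sha256(json.dumps(meta, sort_keys=True).encode()).hexdigest()[:16]


def init_params(seed: int, group_conv_depth: int = 1, channels: int = FUSION_CHANNELS,
                dtype=np.float32) -> NetworkParams:
    """Seeded fan-in-scaled uniform initialization of every layer.

    Kernels and biases are drawn from U(-1/sqrt(fan_in), 1/sqrt(fan_in)),
    the conventional default for small convolutional autoencoders; a fixed
    seed yields bitwise-identical parameters.
    """
    rng = np.random.default_rng(seed)
    weights, biases = {}, {}
    for spec in layer_inventory(group_conv_depth, channels):
        fan_in = spec.in_channels * spec.kernel_size ** 2
        bound = 1.0 / np.sqrt(fan_in)
        shape = (spec.out_channels, spec.in_channels, spec.kernel_size, spec.kernel_size)
        weights[spec.name] = rng.uniform(-bound, bound, size=shape).astype(dtype)
        biases[spec.name] = rng.uniform(-bound, bound, size=spec.out_channels).astype(dtype)
    return NetworkParams(weights, biases, seed=seed,
                         group_conv_depth=group_conv_depth, channels=channels)


# ---------------------------------------------------------------------------
# forward / backward plumbing

def _layer(x, p: NetworkParams, name: str, activation: str, cache):
    y, cols = conv2d_forward(x, p.weights[name], p.biases[name])
    mask = None
    if activation == "relu":
        y, mask = relu_forward(y)
    if cache is not None:
        cache[name] = (x, cols, mask)
    return y


def _layer_backward(gy, p: NetworkParams, name: str, cache, grads):
    x, cols, mask = cache[name]
    if mask is not None:
        gy = relu_backward(gy, mask)
    gx, gw, gb = conv2d_backward(gy, x, p.weights[name], cols)
    grads[f"{name}.weight"] = grads.get(f"{name}.weight", 0) + gw
    grads[f"{name}.bias"] = grads.get(f"{name}.bias", 0) + gb
    return gx


def _group_names(p: NetworkParams, i: int) -> list[str]:
    if p.group_conv_depth == 1:
        return [f"block_h{i}"]
    return [f"block_h{i}_{d + 1}" for d in range(p.group_conv_depth)]


def _block_forward(x, p: NetworkParams, cache):
    z = _layer(x, p, "block_squeeze", "relu", cache)
    g = p.channels // N_GROUPS
    groups = [z[:, i * g : (i + 1) * g] for i in range(N_GROUPS)]
    ys = [groups[0]]
    prev = None
    for i in range(2, N_GROUPS + 1):
        h_in = groups[i - 1] if prev is None else groups[i - 1] + prev
        out = h_in
        for name in _group_names(p, i):
            out = _layer(out, p, name, "relu", cache)
        ys.append(out)
        prev = out
    cat = np.concatenate(ys, axis=1)
    return _layer(cat, p, "block_expand", "relu", cache)


def _block_backward(gy, p: NetworkParams, cache, grads):
    g = p.channels // N_GROUPS
    g_cat = _layer_backward(gy, p, "block_expand", cache, grads)
    g_ys = [g_cat[:, i * g : (i + 1) * g] for i in range(N_GROUPS)]
    g_groups = [None] * N_GROUPS
    carry = None  # gradient flowing from y_{i} back into y_{i-1} via the residual
    for i in range(N_GROUPS, 1, -1):
        gy_i = g_ys[i - 1] if carry is None else g_ys[i - 1] + carry
        for name in reversed(_group_names(p, i)):
            gy_i = _layer_backward(gy_i, p, name, cache, grads)
        g_groups[i - 1] = gy_i  # grad w.r.t. (x_i + y_{i-1})
        carry = gy_i if i > 2 else None
    g_groups[0] = g_ys[0]
    gz = np.concatenate(g_groups, axis=1)
    return _layer_backward(gz, p, "block_squeeze", cache, grads)


def _extract_forward(x, p: NetworkParams, cache):
    h = _layer(x, p, "enc_conv1", "relu", cache)
    h = _layer(h, p, "enc_conv2", "relu", cache)
    return _block_forward(h, p, cache)


def _reconstruct_forward(f, p: NetworkParams, cache):
    h = _layer(f, p, "dec_conv1", "relu", cache)
    h = _layer(h, p, "dec_conv2", "relu", cache)
    h = _layer(h, p, "dec_conv3", "relu", cache)
    return _layer(h, p, "dec_conv4", "none", cache)


def autoencoder_forward(x: np.ndarray, p: NetworkParams, record: bool = False):
    """Extractor + reconstructor on a (B, 1, H, W) batch — no fusion layer.

    Returns the *pre-clamp* reconstruction (the training loss sees the raw
    linear output of the final convolution) and, when ``record``, the cache
    needed by :func:`autoencoder_backward`.
    """
    cache: dict | None = {} if record else None
    feats = _extract_forward(x, p, cache)
    out = _reconstruct_forward(feats, p, cache)
    return out, cache


def autoencoder_backward(g_out: np.ndarray, p: NetworkParams, cache: dict) -> dict:
    """Backpropagate a gradient w.r.t. the reconstruction through all layers."""
    grads: dict = {}
    gf = g_out
    for name in ("dec_conv4", "dec_conv3", "dec_conv2", "dec_conv1"):
        gf = _layer_backward(gf, p, name, cache, grads)
    gh = _block_backward(gf, p, cache, grads)
    gh = _layer_backward(gh, p, "enc_conv2", cache, grads)
    _layer_backward(gh, p, "enc_conv1", cache, grads)
    return grads


# ---------------------------------------------------------------------------
# public single-image operations

def _as_batch(values: np.ndarray, dtype) -> np.ndarray:
    return values[None].astype(dtype, copy=False)


def res2net_block(f: FeatureMap, p: NetworkParams) -> FeatureMap:
    """Apply the hierarchical-residual Res2Net block to a feature map."""
    v = np.asarray(f.values)
    if v.shape[0] != p.channels:
        raise ValueError(f"expected {p.channels} channels, got {v.shape[0]}")
    if v.shape[1] < 3 or v.shape[2] < 3:
        raise ValueError(f"spatial size {v.shape[1:]} too small for 3x3 group convolutions")
    out = _block_forward(_as_batch(v, np.float32), p, None)[0]
    return FeatureMap(out, stage="res2net_block")


def extract_features(img: Image, p: NetworkParams) -> FeatureMap:
    """Run the full feature extractor (two 3x3 convs + Res2Net block)."""
    if not isinstance(img, Image):
        img = Image(np.asarray(img))
    img.require_min_size(MIN_IMAGE_SIZE)
    x = _as_batch(img.pixels[None], np.float32)
    feats = _extract_forward(x, p, None)[0]
    return FeatureMap(feats, stage="extractor")


def reconstruct(f: FeatureMap, p: NetworkParams) -> Image:
    """Decode a 64-channel feature map back to an image, clamped to [0, 1]."""
    v = np.asarray(f.values if isinstance(f, FeatureMap) else f)
    if v.ndim != 3 or v.shape[0] != p.channels:
        raise ValueError(f"expected {p.channels} x H x W features, got shape {v.shape}")
    out = _reconstruct_forward(_as_batch(v, np.float32), p, None)[0, 0]
    return Image(np.clip(out.astype(np.float64), 0.0, 1.0), source_tag=SourceTag.FUSED)


# ---------------------------------------------------------------------------
# checkpointing

def save_checkpoint(p: NetworkParams, path) -> None:
    """Write all layer tensors plus seed/config metadata to an .npz archive."""
    arrays = {f"weight/{n}": w for n, w in p.weights.items()}
    arrays.update({f"bias/{n}": b for n, b in p.biases.items()})
    arrays["meta/seed"] = np.array(p.seed)
    arrays["meta/group_conv_depth"] = np.array(p.group_conv_depth)
    arrays["meta/channels"] = np.array(p.channels)
    arrays["meta/config_hash"] = np.frombuffer(p.config_hash().encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> NetworkParams:
    with np.load(path) as data:
        p = NetworkParams(
            weights={n.split("/", 1)[1]: data[n] for n in data.files if n.startswith("weight/")},
            biases={n.split("/", 1)[1]: data[n] for n in data.files if n.startswith("bias/")},
            seed=int(data["meta/seed"]),
            group_conv_depth=int(data["meta/group_conv_depth"]),
            channels=int(data["meta/channels"]),
        )
    expected = {s.name for s in p.inventory}
    if set(p.weights) != expected:
        raise ValueError("checkpoint layer inventory does not match the architecture")
    return p
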