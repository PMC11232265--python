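"""Two-phase training protocol.

Phase 1 trains the feature extractor and reconstructor as a plain
reconstruction autoencoder — the fusion layer never appears in the training
graph.  Each batch runs image -> extract -> reconstruct -> hybrid loss
(SSIM + pixel), with Adam updates at the configured learning rate.

Phase 2 is inference only: with the trained weights frozen, the
parameter-free fusion layer is inserted between extractor and
reconstructor, and registered CT/MR pairs are fused by
:func:`fuse_pair`.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .fusion import fuse as fuse_strategy
from .image import Image, SourceTag
from .losses import hybrid_loss_grad
from .network import (NetworkParams, autoencoder_backward, autoencoder_forward,
                      init_params, reconstruct)
from .network import _extract_forward, _reconstruct_forward  # internal fast paths

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainHistory", "make_crops", "train_autoencoder", "fuse_pair"]


@dataclass
class TrainConfig:
    """Hyper-parameters of the autoencoder phase.

    Defaults follow the published protocol where stated (learning rate
    1e-4, batch size 4, 256x256 crops); epochs and optimizer are
    config-driven.
    """

    learning_rate: float = 1e-4
    batch_size: int = 4
    crop_size: int = 256
    epochs: int = 30
    seed: int = 0
    optimizer_name: str = "adam"
    device: str = "cpu"

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.crop_size < 32 or self.crop_size % 2:
            raise ValueError("crop_size must be even and >= 32")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.optimizer_name != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer_name!r}")


@dataclass
class TrainHistory:
    """Per-epoch mean losses and wall-clock times of one training run."""

    total: list = field(default_factory=list)
    ssim: list = field(default_factory=list)
    pixel: list = field(default_factory=list)
    seconds: list = field(default_factory=list)
    checkpoint: str | None = None

    @property
    def n_epochs(self) -> int:
        return len(self.total)


def make_crops(images, crop_size: int, seed: int):
    """One random crop_size x crop_size crop per image; deterministic per seed.

    Images smaller than the crop in either dimension are skipped with a
    logged warning; an image exactly at the crop size passes through whole.
    """
    rng = np.random.default_rng(seed)
    crops = []
    for idx, img in enumerate(images):
        arr = img.pixels if isinstance(img, Image) else np.asarray(img, dtype=np.float64)
        h, w = arr.shape
        if h < crop_size or w < crop_size:
            logger.warning("skipping image %d: size %dx%d below crop size %d",
                           idx, h, w, crop_size)
            continue
        top = int(rng.integers(0, h - crop_size + 1))
        left = int(rng.integers(0, w - crop_size + 1))
        tag = img.source_tag if isinstance(img, Image) else SourceTag.OTHER
        crops.append(Image(arr[top : top + crop_size, left : left + crop_size],
                           source_tag=tag))
    return crops


def train_autoencoder(dataset, cfg: TrainConfig):
    """Train extractor + reconstructor to reproduce single images.

    ``dataset`` is a pool of :class:`Image` (CT and MR mixed); each epoch
    takes one fresh random crop per image, shuffles, and steps Adam on the
    hybrid loss.  Fully seeded: initialization, crop offsets and shuffling
    all derive from ``cfg.seed``.  Returns ``(NetworkParams, TrainHistory)``.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty training dataset")
    from .nn import Adam

    params = init_params(cfg.seed)
    optimizer = Adam(params.trainable(), lr=cfg.learning_rate)
    history = TrainHistory()
    rng = np.random.default_rng((cfg.seed, 0xA5))
    for epoch in range(cfg.epochs):
        t0 = time.perf_counter()
        crops = make_crops(dataset, cfg.crop_size, seed=int(rng.integers(2 ** 31 - 1)))
        if not crops:
            raise ValueError("no image in the dataset is large enough to crop")
        order = rng.permutation(len(crops))
        totals, ssims, pixels = [], [], []
        for start in range(0, len(order), cfg.batch_size):
            batch_idx = order[start : start + cfg.batch_size]
            x = np.stack([crops[i].pixels for i in batch_idx])[:, None].astype(np.float32)
            out, cache = autoencoder_forward(x, params, record=True)
            loss, grad = hybrid_loss_grad(out, x)
            if not np.isfinite(loss.total):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}: "
                    f"{loss}"
                )
            grads = autoencoder_backward(grad.astype(np.float32), params, cache)
            optimizer.step(grads)
            totals.append(loss.total)
            ssims.append(loss.ssim_term)
            pixels.append(loss.pixel_term)
        history.total.append(float(np.mean(totals)))
        history.ssim.append(float(np.mean(ssims)))
        history.pixel.append(float(np.mean(pixels)))
        history.seconds.append(time.perf_counter() - t0)
        logger.info("epoch %d/%d: loss %.5f (ssim %.5f, pixel %.5f) in %.1fs",
                    epoch + 1, cfg.epochs, history.total[-1], history.ssim[-1],
                    history.pixel[-1], history.seconds[-1])
    return params, history


def fuse_pair(ct, mr, params: NetworkParams, strategy: str = "mean_attention",
              **strategy_kwargs) -> Image:
    """Fuse one registered CT/MR pair with the trained weights.

    Features are extracted from each source, combined by the selected
    fusion strategy, and decoded by the reconstructor; the result is an
    :class:`Image` in [0, 1] of the same size as the inputs.
    """
    ct_img = ct if isinstance(ct, Image) else Image(np.asarray(ct))
    mr_img = mr if isinstance(mr, Image) else Image(np.asarray(mr))
    if ct_img.shape != mr_img.shape:
        raise ValueError(
            f"CT ({ct_img.shape}) and MR ({mr_img.shape}) differ in size; "
            "inputs must be pre-registered to the same grid"
        )
    ct_img.require_min_size(8)
    feats = []
    for img in (ct_img, mr_img):
        x = img.pixels[None, None].astype(np.float32)
        feats.append(_extract_forward(x, params, None)[0])
    fused = fuse_strategy(feats, strategy=strategy, **strategy_kwargs)
    return reconstruct(fused, params)
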