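"""Synthetic registered CT/MR head-slice phantoms.

Real MR-CT training data for this kind of fusion model is clinical and not
shareable, so the package ships a seeded generator of registered pairs
that reproduces the modality contrast the fusion method exploits:

- CT: bright high-intensity skull ring (high electron density), low
  soft-tissue contrast, lesions barely distinguishable from brain.
- MR: dark skull, high soft-tissue signal with smooth random texture, and
  high-contrast bright lesions with sharp boundaries.

A phantom is a label map (background / skull / soft tissue / ventricle /
tumor) drawn from randomized ellipse geometry; both modality renders share
the label map, so every pair is registered by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .image import Image, SourceTag

__all__ = [
    "LABELS", "AnatomyPhantom", "generate_anatomy", "render_ct", "render_mr",
    "generate_dataset",
]

LABELS = {"background": 0, "skull": 1, "soft_tissue": 2, "ventricle": 3, "tumor": 4}

# modality intensity assignments (unit scale, before smoothing/noise)
CT_LEVELS = {"background": 0.0, "skull": 0.95, "soft_tissue": 0.35,
             "ventricle": 0.25, "tumor": 0.38}
MR_LEVELS = {"background": 0.0, "skull": 0.05, "soft_tissue": 0.55,
             "ventricle": 0.20, "tumor": 0.85}

# partial-volume blur at tissue boundaries; kept mild so the thin skull
# ring retains its high CT intensity
_RENDER_SMOOTH_SIGMA = 0.4


@dataclass
class AnatomyPhantom:
    """A labelled 2-D head slice plus the geometry that produced it."""

    label_map: np.ndarray
    seed: int
    head_axes: tuple[float, float]
    skull_thickness: float
    tumors: list  # list of (cy, cx, radius)

    @property
    def size(self) -> int:
        return self.label_map.shape[0]

    def mask(self, name: str) -> np.ndarray:
        return self.label_map == LABELS[name]


def _ellipse(shape, center, axes, angle) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - center[0], xx - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    return (u / axes[1]) ** 2 + (v / axes[0]) ** 2 <= 1.0


def generate_anatomy(size: int, seed: int) -> AnatomyPhantom:
    """Draw a random head phantom: skull ring, brain, ventricle, 0-2 tumors.

    Deterministic per seed.  Skull thickness is 2-6 px; tumor radii are
    5-15 % of the image size and tumors lie strictly inside soft tissue.
    """
    if size < 64:
        raise ValueError(f"phantom size must be >= 64, got {size}")
    rng = np.random.default_rng(seed)
    center = (size / 2 + rng.uniform(-0.03, 0.03) * size,
              size / 2 + rng.uniform(-0.03, 0.03) * size)
    axes = (rng.uniform(0.34, 0.42) * size, rng.uniform(0.34, 0.42) * size)
    angle = rng.uniform(0, np.pi)
    thickness = rng.uniform(2.0, 6.0)

    head = _ellipse((size, size), center, axes, angle)
    inner = _ellipse((size, size), center, (axes[0] - thickness, axes[1] - thickness), angle)
    labels = np.zeros((size, size), dtype=np.int64)
    labels[head] = LABELS["skull"]
    labels[inner] = LABELS["soft_tissue"]

    # ventricle: small off-center ellipse well inside the brain
    v_axes = (rng.uniform(0.04, 0.08) * size, rng.uniform(0.06, 0.12) * size)
    v_center = (center[0] + rng.uniform(-0.06, 0.06) * size,
                center[1] + rng.uniform(-0.06, 0.06) * size)
    ventricle = _ellipse((size, size), v_center, v_axes, rng.uniform(0, np.pi)) & inner
    labels[ventricle] = LABELS["ventricle"]

    tumors = []
    n_tumors = int(rng.integers(0, 3))
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(n_tumors):
        for _attempt in range(50):
            radius = rng.uniform(0.05, 0.15) * size
            cy = center[0] + rng.uniform(-0.2, 0.2) * size
            cx = center[1] + rng.uniform(-0.2, 0.2) * size
            disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
            # strictly inside soft tissue: a 2 px guard band keeps the lesion
            # clear of skull, background, ventricle and other tumors
            guard = (yy - cy) ** 2 + (xx - cx) ** 2 <= (radius + 2.0) ** 2
            if disc.any() and np.all(labels[guard] == LABELS["soft_tissue"]):
                labels[disc] = LABELS["tumor"]
                tumors.append((float(cy), float(cx), float(radius)))
                break

    return AnatomyPhantom(label_map=labels, seed=seed, head_axes=axes,
                          skull_thickness=float(thickness), tumors=tumors)


def _render(ph: AnatomyPhantom, levels: dict, noise_sd: float, rng_salt: int,
            texture=None) -> np.ndarray:
    img = np.zeros(ph.label_map.shape, dtype=np.float64)
    for name, value in levels.items():
        img[ph.mask(name)] = value
    if texture is not None:
        img += texture
    img = gaussian_filter(img, _RENDER_SMOOTH_SIGMA)
    if noise_sd > 0:
        rng = np.random.default_rng((ph.seed, rng_salt))
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0)


def render_ct(ph: AnatomyPhantom, noise_sd: float = 0.01) -> Image:
    """CT render: bright skull, flat low-contrast soft tissue and lesions."""
    return Image(_render(ph, CT_LEVELS, noise_sd, rng_salt=1),
                 source_tag=SourceTag.CT)


# correlation length (px) of the MR soft-tissue texture field; short, so the
# render shows the fine-grained tissue texture characteristic of T1 MR
_MR_TEXTURE_SIGMA = 1.5


def render_mr(ph: AnatomyPhantom, noise_sd: float = 0.01,
              texture_amp: float = 0.15) -> Image:
    """MR render: dark skull, finely textured soft tissue, bright sharp lesions."""
    texture = None
    if texture_amp > 0:
        rng = np.random.default_rng((ph.seed, 2))
        field = gaussian_filter(rng.normal(0.0, 1.0, ph.label_map.shape),
                                _MR_TEXTURE_SIGMA)
        field /= max(np.abs(field).max(), 1e-12)
        texture = texture_amp * field * ph.mask("soft_tissue")
    return Image(_render(ph, MR_LEVELS, noise_sd, rng_salt=3, texture=texture),
                 source_tag=SourceTag.MR)


def generate_dataset(n_pairs: int, size: int = 96, seed: int = 0,
                     noise_sd: float = 0.01, texture_amp: float = 0.15):
    """n registered (ct, mr, phantom) triples from n distinct phantoms.

    Per-pair sub-seeds derive deterministically from the master seed and
    stay below 2**31.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2 ** 31 - 1, size=n_pairs)
    out = []
    for s in sub_seeds:
        ph = generate_anatomy(size, int(s))
        out.append((render_ct(ph, noise_sd), render_mr(ph, noise_sd, texture_amp), ph))
    return out
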