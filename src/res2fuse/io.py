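"""Image readers/writers and manifest handling.

Supported inputs: 8/16-bit grayscale PNG and TIFF (via imageio) and NIfTI
volumes with a ``path#z`` slice selector (via nibabel).  Intensities are
scaled to [0, 1] by the format maximum and the gray-level count is recorded
on the :class:`~res2fuse.image.Image` for histogram metrics.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .image import Image, SourceTag

logger = logging.getLogger(__name__)

__all__ = ["read_image", "write_image", "Manifest"]

_LUMA = np.array([0.299, 0.587, 0.114])


def _split_slice_selector(path: str):
    s = str(path)
    if "#" in s:
        base, _, z = s.rpartition("#")
        return base, int(z)
    return s, None


def read_image(path, source_tag: SourceTag = SourceTag.OTHER) -> Image:
    """Read a grayscale image (or one NIfTI slice) as an [0, 1] Image."""
    base, z = _split_slice_selector(path)
    p = Path(base)
    if not p.exists():
        raise FileNotFoundError(f"image file not found: {p}")
    suffixes = "".join(p.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        vol = np.asanyarray(nib.load(p).dataobj)
        if vol.ndim == 3:
            if z is None:
                z = vol.shape[2] // 2
                logger.warning("no #z slice selector for %s; using middle slice %d", p, z)
            arr = np.asarray(vol[:, :, z], dtype=np.float64)
        elif vol.ndim == 2:
            arr = np.asarray(vol, dtype=np.float64)
        else:
            raise ValueError(f"unsupported NIfTI dimensionality {vol.ndim} in {p}")
        # NIfTI carries no canonical integer range; normalize by the volume max
        vmax = float(np.max(np.abs(vol))) or 1.0
        return Image(np.clip(arr, 0, None) / vmax, levels=256, source_tag=source_tag)
    try:
        raw = iio.imread(p)
    except Exception as exc:  # pragma: no cover - backend specific
        raise ValueError(f"cannot read image file {p}: {exc}") from exc
    if raw.ndim == 3:
        logger.warning("%s is RGB; converting to luminance", p)
        raw = raw[..., :3].astype(np.float64) @ _LUMA
        levels = 256
        arr = raw / 255.0
    elif raw.dtype == np.uint8:
        levels = 256
        arr = raw.astype(np.float64) / 255.0
    elif raw.dtype == np.uint16:
        levels = 65536
        arr = raw.astype(np.float64) / 65535.0
    elif np.issubdtype(raw.dtype, np.floating):
        levels = 256
        arr = np.clip(raw.astype(np.float64), 0.0, 1.0)
    else:
        raise ValueError(f"unsupported pixel type {raw.dtype} in {p}")
    return Image(np.clip(arr, 0.0, 1.0), levels=levels, source_tag=source_tag)


def write_image(img: Image, path, bit_depth: int = 8) -> None:
    """Quantize to 8 or 16 bits (round half away from zero) and write losslessly."""
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    maxv = 2 ** bit_depth - 1
    arr = img.pixels if isinstance(img, Image) else np.asarray(img, dtype=np.float64)
    q = np.floor(arr * maxv + 0.5)  # values are >= 0, so half-up == half-away
    q = np.clip(q, 0, maxv).astype(np.uint8 if bit_depth == 8 else np.uint16)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, q)


class Manifest:
    """CSV-backed list of (ct_path, mr_path [, fused_path, label_path]) rows."""

    COLUMNS = ("ct_path", "mr_path", "fused_path", "label_path")

    def __init__(self, frame: pd.DataFrame, root: Path | None = None):
        if "ct_path" not in frame.columns or "mr_path" not in frame.columns:
            raise ValueError("manifest needs at least ct_path and mr_path columns")
        self.frame = frame.reset_index(drop=True)
        self.root = Path(root) if root is not None else Path(".")

    @classmethod
    def read(cls, path) -> "Manifest":
        path = Path(path)
        return cls(pd.read_csv(path), root=path.parent)

    def write(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.frame.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.frame)

    def resolve(self, value: str) -> Path:
        p = Path(str(value).split("#")[0])
        return p if p.is_absolute() else self.root / p

    def validate(self) -> None:
        """Check referenced files exist and each row's pair shares dimensions."""
        for i, row in self.frame.iterrows():
            for col in self.COLUMNS:
                if col in row and isinstance(row[col], str) and row[col]:
                    target = self.resolve(row[col])
                    if not target.exists():
                        raise FileNotFoundError(f"manifest row {i}: missing {target}")
            ct = read_image(self._full(row["ct_path"]))
            mr = read_image(self._full(row["mr_path"]))
            if ct.shape != mr.shape:
                raise ValueError(
                    f"manifest row {i}: CT {ct.shape} and MR {mr.shape} differ in size"
                )

    def _full(self, value: str) -> str:
        base, _, z = str(value).partition("#")
        resolved = str(self.resolve(base))
        return f"{resolved}#{z}" if z else resolved

    def iter_pairs(self):
        """Yield (ct Image, mr Image, optional fused Image) per row."""
        for _, row in self.frame.iterrows():
            ct = read_image(self._full(row["ct_path"]), SourceTag.CT)
            mr = read_image(self._full(row["mr_path"]), SourceTag.MR)
            fused = None
            if "fused_path" in row and isinstance(row["fused_path"], str) and row["fused_path"]:
                fused = read_image(self._full(row["fused_path"]), SourceTag.FUSED)
            yield ct, mr, fused
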