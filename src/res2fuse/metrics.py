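"""Objective quality metrics for image fusion.

Eight indices, each comparing a fused image F against its two registered
sources A and B (CT and MR):

- AG   average gradient: mean magnitude of forward differences; sharpness.
- SF   spatial frequency: RMS of row/column first differences.
- EN   Shannon entropy (bits) of the quantized intensity histogram.
- MI   histogram mutual information retained from the sources.
- PSNR peak signal-to-noise ratio against the mean of the two source MSEs.
- SSIM mean windowed structural similarity against each source.
- Qabf Xydeas-Petrovic edge-preservation index from Sobel strength and
  orientation agreement.
- VIFF multi-scale visual-information-fidelity fusion measure.

Gradient metrics (AG, SF) operate on the [0, 1] intensity scale; histogram
metrics quantize to ``levels`` gray levels (default 256); VIFF evaluates on
the 0-255 scale, on which its additive-noise variance constant is defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .image import Image, as_pixels
from .losses import gaussian_window, ssim_map

__all__ = [
    "average_gradient", "spatial_frequency", "entropy", "mutual_information",
    "psnr", "ssim_fusion", "qabf", "viff",
    "MetricReport", "evaluate_pair", "evaluate_batch", "paired_t_test",
    "METRIC_NAMES",
]

METRIC_NAMES = ("ag", "sf", "en", "mi", "psnr", "ssim", "qabf", "viff")


# ---------------------------------------------------------------------------
# sharpness / texture

def average_gradient(f) -> float:
    """Mean RMS of the two forward differences over the (M-1)x(N-1) grid."""
    arr = as_pixels(f)
    dv = arr[1:, :-1] - arr[:-1, :-1]   # F(i+1, j) - F(i, j)
    dh = arr[:-1, 1:] - arr[:-1, :-1]   # F(i, j+1) - F(i, j)
    return float(np.mean(np.sqrt((dv ** 2 + dh ** 2) / 2.0)))


def spatial_frequency(f) -> float:
    """sqrt(RF^2 + CF^2) of row/column first differences, normalized by MN."""
    arr = as_pixels(f)
    m, n = arr.shape
    rf2 = np.sum((arr[:, 1:] - arr[:, :-1]) ** 2) / (m * n)
    cf2 = np.sum((arr[1:, :] - arr[:-1, :]) ** 2) / (m * n)
    return float(np.sqrt(rf2 + cf2))


# ---------------------------------------------------------------------------
# histogram information

def _levels_of(img, levels: int | None) -> int:
    if levels is not None:
        return levels
    return img.levels if isinstance(img, Image) else 256


def _quantize(arr: np.ndarray, levels: int) -> np.ndarray:
    return np.clip(np.rint(arr * (levels - 1)), 0, levels - 1).astype(np.int64)


def entropy(f, levels: int | None = None) -> float:
    """Shannon entropy (bits) of the quantized histogram; 0 log 0 := 0."""
    lv = _levels_of(f, levels)
    q = _quantize(as_pixels(f), lv)
    p = np.bincount(q.ravel(), minlength=lv) / q.size
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def _joint_entropy(qa: np.ndarray, qb: np.ndarray, levels: int) -> float:
    joint = np.bincount(qa.ravel() * levels + qb.ravel(), minlength=levels * levels)
    p = joint / qa.size
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def _mi_pair(qa: np.ndarray, qb: np.ndarray, levels: int) -> float:
    ha = entropy(qa / (levels - 1), levels)
    hb = entropy(qb / (levels - 1), levels)
    return ha + hb - _joint_entropy(qa, qb, levels)


def mutual_information(f, a, b, mode: str = "fusion_standard",
                       levels: int | None = None) -> float:
    """Histogram mutual information.

    ``fusion_standard`` (default): MI(A; F) + MI(B; F) — the information
    the fused image retains from each source.  ``pair_literal``: MI(A; B)
    between the two sources only.
    """
    lv = _levels_of(f, levels)
    qf, qa, qb = (_quantize(as_pixels(x), lv) for x in (f, a, b))
    if qf.shape != qa.shape or qf.shape != qb.shape:
        raise ValueError("images must share the same shape")
    if mode == "fusion_standard":
        return _mi_pair(qa, qf, lv) + _mi_pair(qb, qf, lv)
    if mode == "pair_literal":
        return _mi_pair(qa, qb, lv)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# fidelity

def psnr(f, a, b, peak: str = "fused_max") -> float:
    """PSNR of the fused image against the averaged source MSE.

    ``peak="fused_max"`` uses the fused image's own peak value r (the
    literal reading of the definition); ``"full_scale"`` uses r = 1.
    Returns ``inf`` when both MSEs vanish.
    """
    ff, fa, fb = as_pixels(f), as_pixels(a), as_pixels(b)
    if ff.shape != fa.shape or ff.shape != fb.shape:
        raise ValueError("images must share the same shape")
    mse = 0.5 * (np.mean((fa - ff) ** 2) + np.mean((fb - ff) ** 2))
    if mse == 0.0:
        return float("inf")
    if peak == "fused_max":
        r = float(ff.max())
    elif peak == "full_scale":
        r = 1.0
    else:
        raise ValueError(f"unknown peak convention {peak!r}")
    return float(10.0 * np.log10(r ** 2 / mse))


def ssim_fusion(f, a, b) -> float:
    """Mean of windowed SSIM(A, F) and SSIM(B, F) (11x11 Gaussian, sigma 1.5)."""
    ff, fa, fb = as_pixels(f), as_pixels(a), as_pixels(b)
    if ff.shape != fa.shape or ff.shape != fb.shape:
        raise ValueError("images must share the same shape")
    win = gaussian_window()
    return float(0.5 * (ssim_map(fa, ff, win).mean() + ssim_map(fb, ff, win).mean()))


# ---------------------------------------------------------------------------
# edge preservation (Xydeas-Petrovic)

_SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])

# sigmoid constants of the standard edge-preservation model
_GAMMA_G, _KAPPA_G, _SIGMA_G = 0.9994, -15.0, 0.5
_GAMMA_A, _KAPPA_A, _SIGMA_A = 0.9879, -22.0, 0.8


def _sobel_edges(arr: np.ndarray):
    gx = ndimage.correlate(arr, _SOBEL_X, mode="nearest")
    gy = ndimage.correlate(arr, _SOBEL_X.T, mode="nearest")
    g = np.hypot(gx, gy)
    alpha = np.arctan2(gy, gx)
    # fold to (-pi/2, pi/2]: edge orientation, not direction
    alpha = np.where(alpha > np.pi / 2, alpha - np.pi, alpha)
    alpha = np.where(alpha <= -np.pi / 2, alpha + np.pi, alpha)
    return g, alpha


def _edge_preservation(gs: np.ndarray, As: np.ndarray, gf: np.ndarray, af: np.ndarray):
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(gs > gf, gf / gs, np.where(gf > 0, gs / gf, 0.0))
    rel = np.nan_to_num(rel)
    ang = 1.0 - np.abs(As - af) / (np.pi / 2.0)
    qg = _GAMMA_G / (1.0 + np.exp(_KAPPA_G * (rel - _SIGMA_G)))
    qa = _GAMMA_A / (1.0 + np.exp(_KAPPA_A * (ang - _SIGMA_A)))
    return qg * qa


def qabf(f, a, b) -> float:
    """Edge-based fusion quality in [0, 1]; symmetric in the two sources."""
    ff, fa, fb = as_pixels(f), as_pixels(a), as_pixels(b)
    if ff.shape != fa.shape or ff.shape != fb.shape:
        raise ValueError("images must share the same shape")
    gf, af = _sobel_edges(ff)
    ga, aa = _sobel_edges(fa)
    gb, ab = _sobel_edges(fb)
    q_af = _edge_preservation(ga, aa, gf, af)
    q_bf = _edge_preservation(gb, ab, gf, af)
    denom = np.sum(ga + gb)
    if denom == 0.0:
        return 0.0
    return float(np.sum(q_af * ga + q_bf * gb) / denom)


# ---------------------------------------------------------------------------
# visual information fidelity for fusion

_VIFF_SIGMA_N_SQ = 2.0          # HVS additive-noise variance on the 0-255 scale
_VIFF_SCALE_WEIGHTS = np.array([0.5, 0.25, 0.15, 0.10])
_VIFF_EPS = 1e-10


def _vif_terms(ref: np.ndarray, dist: np.ndarray, win: np.ndarray):
    """Per-position numerator/denominator log terms of pixel-domain VIF."""
    from scipy.signal import fftconvolve

    mu_r = fftconvolve(ref, win, mode="valid")
    mu_d = fftconvolve(dist, win, mode="valid")
    var_r = np.clip(fftconvolve(ref * ref, win, mode="valid") - mu_r ** 2, 0.0, None)
    var_d = np.clip(fftconvolve(dist * dist, win, mode="valid") - mu_d ** 2, 0.0, None)
    cov = fftconvolve(ref * dist, win, mode="valid") - mu_r * mu_d
    g = cov / (var_r + _VIFF_EPS)
    sv = var_d - g * cov
    g = np.clip(g, 0.0, None)
    sv = np.clip(sv, _VIFF_EPS, None)
    num = np.log10(1.0 + g ** 2 * var_r / (sv + _VIFF_SIGMA_N_SQ))
    den = np.log10(1.0 + var_r / _VIFF_SIGMA_N_SQ)
    return num, den


def viff(f, a, b) -> float:
    """Multi-scale visual-information-fidelity fusion measure.

    At each of four Gaussian-pyramid scales, Gaussian-windowed local
    statistics give per-position VIF information terms for each source
    against the fused image; at every position the source carrying more
    reference information (larger denominator term) is selected, and the
    selected terms are aggregated into a per-scale fidelity ratio.  Scales
    are combined with fixed decreasing weights.  Equals 1 when the fused
    image coincides with both sources.
    """
    ff, fa, fb = (255.0 * as_pixels(x, min_size=32) for x in (f, a, b))
    if ff.shape != fa.shape or ff.shape != fb.shape:
        raise ValueError("images must share the same shape")
    ratios = []
    for scale in range(1, 5):
        n = 2 ** (4 - scale + 1) + 1
        win = gaussian_window(n, n / 5.0)
        if scale > 1:
            ff, fa, fb = (_decimate(x, win) for x in (ff, fa, fb))
        num_a, den_a = _vif_terms(fa, ff, win)
        num_b, den_b = _vif_terms(fb, ff, win)
        pick_a = den_a >= den_b
        num = np.where(pick_a, num_a, num_b).sum()
        den = np.where(pick_a, den_a, den_b).sum()
        ratios.append(num / den if den > 0 else 1.0)
    w = _VIFF_SCALE_WEIGHTS / _VIFF_SCALE_WEIGHTS.sum()
    return float(np.dot(w, ratios))


def _decimate(x: np.ndarray, win: np.ndarray) -> np.ndarray:
    """Low-pass filter (same-size, symmetric padding) and downsample by 2."""
    return ndimage.correlate(x, win, mode="reflect")[::2, ::2]


# ---------------------------------------------------------------------------
# reports

@dataclass
class MetricReport:
    """All eight metrics for one fused image against its two sources."""

    ag: float
    sf: float
    en: float
    mi: float
    psnr: float
    ssim: float
    qabf: float
    viff: float
    sources: tuple[str, str] = ("a", "b")
    fused: str = "fused"

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_NAMES}


def evaluate_pair(f, a, b, mi_mode: str = "fusion_standard",
                  psnr_peak: str = "fused_max", labels=None) -> MetricReport:
    """Assemble the full eight-metric report for one (fused, CT, MR) triple."""
    return MetricReport(
        ag=average_gradient(f),
        sf=spatial_frequency(f),
        en=entropy(f),
        mi=mutual_information(f, a, b, mode=mi_mode),
        psnr=psnr(f, a, b, peak=psnr_peak),
        ssim=ssim_fusion(f, a, b),
        qabf=qabf(f, a, b),
        viff=viff(f, a, b),
        sources=tuple(labels[:2]) if labels else ("a", "b"),
        fused=labels[2] if labels and len(labels) > 2 else "fused",
    )


def evaluate_batch(triples, **kwargs) -> pd.DataFrame:
    """Metric table over (fused, a, b) triples, with a final ``mean`` row."""
    triples = list(triples)
    if not triples:
        raise ValueError("empty batch of image triples")
    rows = [evaluate_pair(f, a, b, **kwargs).as_dict() for f, a, b in triples]
    df = pd.DataFrame(rows, index=[f"pair_{i}" for i in range(len(rows))])
    df.loc["mean"] = df.mean(axis=0)
    return df


def paired_t_test(col_x, col_y):
    """Two-sided paired t-test between two per-image metric columns.

    Zero-variance differences are degenerate for the t statistic; following
    the documented convention, the test then reports p = 0 for a nonzero
    mean difference and (t, p) = (0, 1) when the columns are identical.
    """
    x = np.asarray(col_x, dtype=np.float64)
    y = np.asarray(col_y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length 1-D columns with n >= 2")
    d = x - y
    if np.std(d) == 0.0:
        warnings.warn("zero-variance paired differences; degenerate t-test",
                      RuntimeWarning, stacklevel=2)
        if d.mean() == 0.0:
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(x, y)
    return float(t), float(p)
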