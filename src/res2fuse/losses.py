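"""Hybrid training loss: structural-similarity term plus pixel (MSE) term.

    L = L_ssim + L_pixel
    L_ssim  = 1 - SSIM(I_fused, I_input)
    L_pixel = ||I_fused - I_input||_2^2 / (B C H W)

SSIM uses the de-facto standard windowed form: an 11x11 Gaussian window
(sigma 1.5), c1 = (0.01 L)^2, c2 = (0.03 L)^2 with dynamic range L = 1 on
normalized intensities, averaged over all fully supported ("valid") window
positions.  Because the surrounding training loop is pure NumPy, the
gradient of the SSIM term with respect to the fused image is provided in
closed form (re-expressing the per-window statistics through the three
filtered moments G*x, G*x^2 and G*(xy) and applying the adjoint — a "full"
correlation — of the window filter); it is validated against finite
differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

__all__ = ["LossValue", "ssim_loss", "pixel_loss", "hybrid_loss", "hybrid_loss_grad",
           "gaussian_window", "ssim_map"]

WINDOW_SIZE = 11
WINDOW_SIGMA = 1.5
C1 = (0.01 * 1.0) ** 2
C2 = (0.03 * 1.0) ** 2


def gaussian_window(size: int = WINDOW_SIZE, sigma: float = WINDOW_SIGMA) -> np.ndarray:
    """Normalized 2-D Gaussian window (sums to 1)."""
    r = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(r ** 2) / (2.0 * sigma ** 2))
    w = np.outer(g, g)
    return w / w.sum()


@dataclass(frozen=True)
class LossValue:
    """Total hybrid loss and its two components (total = ssim + pixel)."""

    total: float
    ssim_term: float
    pixel_term: float


def _as_batch(x) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[:, None]
    elif arr.ndim != 4:
        raise ValueError(f"expected (B, C, H, W), got shape {arr.shape}")
    return arr


def _check_pair(fused, inp):
    f, x = _as_batch(fused), _as_batch(inp)
    if f.shape != x.shape:
        raise ValueError(f"shape mismatch: fused {f.shape} vs input {x.shape}")
    return f, x


def _moments(x, y, win):
    mu_x = fftconvolve(x, win, mode="valid")
    mu_y = fftconvolve(y, win, mode="valid")
    m_xx = fftconvolve(x * x, win, mode="valid")
    m_yy = fftconvolve(y * y, win, mode="valid")
    m_xy = fftconvolve(x * y, win, mode="valid")
    return mu_x, mu_y, m_xx - mu_x ** 2, m_yy - mu_y ** 2, m_xy - mu_x * mu_y


def ssim_map(x: np.ndarray, y: np.ndarray, win: np.ndarray | None = None) -> np.ndarray:
    """Per-window SSIM between two 2-D images (valid positions only)."""
    if win is None:
        win = gaussian_window()
    mu_x, mu_y, var_x, var_y, cov = _moments(
        np.asarray(x, dtype=np.float64), np.asarray(y, dtype=np.float64), win
    )
    a1 = 2.0 * mu_x * mu_y + C1
    a2 = 2.0 * cov + C2
    b1 = mu_x ** 2 + mu_y ** 2 + C1
    b2 = var_x + var_y + C2
    return (a1 * a2) / (b1 * b2)


def ssim_loss(fused, inp) -> float:
    """1 - SSIM(fused, input), averaged over batch and channels; in [0, 2]."""
    f, x = _check_pair(fused, inp)
    win = gaussian_window()
    vals = [ssim_map(f[b, c], x[b, c], win).mean()
            for b in range(f.shape[0]) for c in range(f.shape[1])]
    return float(1.0 - np.mean(vals))


def pixel_loss(fused, inp) -> float:
    """Mean squared element-wise difference (Frobenius norm over B*C*H*W)."""
    f, x = _check_pair(fused, inp)
    return float(np.mean((f - x) ** 2))


def hybrid_loss(fused, inp) -> LossValue:
    """Unit-weighted sum of the SSIM and pixel terms."""
    s = ssim_loss(fused, inp)
    p = pixel_loss(fused, inp)
    return LossValue(total=s + p, ssim_term=s, pixel_term=p)


def _ssim_grad_single(x: np.ndarray, y: np.ndarray, win: np.ndarray):
    """Mean SSIM over valid windows and its gradient w.r.t. x (2-D images)."""
    mu_x, mu_y, var_x, var_y, cov = _moments(x, y, win)
    a1 = 2.0 * mu_x * mu_y + C1
    a2 = 2.0 * cov + C2
    b1 = mu_x ** 2 + mu_y ** 2 + C1
    b2 = var_x + var_y + C2
    s = (a1 * a2) / (b1 * b2)
    n_win = s.size

    # partials of S w.r.t. the filtered moments mu_x, G*x^2 and G*(xy);
    # sigma_x^2 = G*x^2 - mu_x^2 and sigma_xy = G*(xy) - mu_x mu_y make
    # mu_x enter A1, A2, B1 and B2 simultaneously.
    d_mu = (2.0 * mu_y * a2 - 2.0 * mu_y * a1) / (b1 * b2) \
        - s * (2.0 * mu_x / b1 - 2.0 * mu_x / b2)
    d_mxx = -s / b2
    d_mxy = 2.0 * a1 / (b1 * b2)

    # adjoint of the valid-mode window filter is full-mode convolution
    t_mu = fftconvolve(d_mu, win, mode="full")
    t_mxx = fftconvolve(d_mxx, win, mode="full")
    t_mxy = fftconvolve(d_mxy, win, mode="full")
    grad = (t_mu + 2.0 * x * t_mxx + y * t_mxy) / n_win
    return s.mean(), grad


def hybrid_loss_grad(fused, inp):
    """Hybrid loss and its gradient with respect to the fused batch.

    Returns ``(LossValue, grad)`` with ``grad`` shaped like the fused input
    (B, C, H, W).  d L_pixel / d f = 2 (f - x) / (B C H W); the SSIM term's
    gradient comes from :func:`_ssim_grad_single`.
    """
    f, x = _check_pair(fused, inp)
    win = gaussian_window()
    b, c = f.shape[:2]
    grad = 2.0 * (f - x) / f.size
    ssim_vals = []
    for bi in range(b):
        for ci in range(c):
            s, g = _ssim_grad_single(f[bi, ci], x[bi, ci], win)
            ssim_vals.append(s)
            grad[bi, ci] += -g / (b * c)
    s_term = float(1.0 - np.mean(ssim_vals))
    p_term = float(np.mean((f - x) ** 2))
    return LossValue(total=s_term + p_term, ssim_term=s_term, pixel_term=p_term), grad
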