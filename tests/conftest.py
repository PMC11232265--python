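"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive (explicit Python loops over pixels,
windows and histogram bins) so they share no code path with the package
implementation they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest


# ---------------------------------------------------------------------------
# loop-based convolution oracle

def conv2d_oracle(x: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Direct nested-loop same-size convolution; x is (C_in, H, W)."""
    c_out, c_in, k, _ = weight.shape
    _, h, w = x.shape
    pad = (k - 1) // 2
    out = np.zeros((c_out, h, w), dtype=np.float64)
    for co in range(c_out):
        for i in range(h):
            for j in range(w):
                acc = float(bias[co])
                for ci in range(c_in):
                    for di in range(k):
                        for dj in range(k):
                            ii, jj = i + di - pad, j + dj - pad
                            if 0 <= ii < h and 0 <= jj < w:
                                acc += float(weight[co, ci, di, dj]) * float(x[ci, ii, jj])
                out[co, i, j] = acc
    return out


def relu_oracle(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def res2net_block_oracle(x: np.ndarray, params) -> np.ndarray:
    """Direct evaluation of the hierarchical-residual block on (C, H, W)."""
    w, b = params.weights, params.biases
    z = relu_oracle(conv2d_oracle(x, w["block_squeeze"], b["block_squeeze"]))
    g = z.shape[0] // 4
    xs = [z[i * g : (i + 1) * g] for i in range(4)]
    ys = [xs[0]]
    prev = None
    for i in range(2, 5):
        inp = xs[i - 1] if prev is None else xs[i - 1] + prev
        names = ([f"block_h{i}"] if params.group_conv_depth == 1
                 else [f"block_h{i}_{d+1}" for d in range(params.group_conv_depth)])
        out = inp
        for name in names:
            out = relu_oracle(conv2d_oracle(out, w[name], b[name]))
        ys.append(out)
        prev = out
    cat = np.concatenate(ys, axis=0)
    return relu_oracle(conv2d_oracle(cat, w["block_expand"], b["block_expand"]))


# ---------------------------------------------------------------------------
# loop-based metric oracles

def average_gradient_oracle(f: np.ndarray) -> float:
    m, n = f.shape
    total = 0.0
    for i in range(m - 1):
        for j in range(n - 1):
            dv = f[i + 1, j] - f[i, j]
            dh = f[i, j + 1] - f[i, j]
            total += math.sqrt((dv * dv + dh * dh) / 2.0)
    return total / ((m - 1) * (n - 1))


def spatial_frequency_oracle(f: np.ndarray) -> float:
    m, n = f.shape
    rf = sum((f[i, j] - f[i, j - 1]) ** 2 for i in range(m) for j in range(1, n))
    cf = sum((f[i, j] - f[i - 1, j]) ** 2 for i in range(1, m) for j in range(n))
    return math.sqrt(rf / (m * n) + cf / (m * n))


def _quantize_oracle(f: np.ndarray, levels: int) -> np.ndarray:
    return np.clip(np.rint(f * (levels - 1)), 0, levels - 1).astype(int)


def entropy_oracle(f: np.ndarray, levels: int = 256) -> float:
    q = _quantize_oracle(f, levels)
    counts = {}
    for v in q.ravel():
        counts[v] = counts.get(v, 0) + 1
    total = q.size
    return -sum((c / total) * math.log2(c / total) for c in counts.values())


def joint_entropy_oracle(a: np.ndarray, b: np.ndarray, levels: int = 256) -> float:
    qa, qb = _quantize_oracle(a, levels), _quantize_oracle(b, levels)
    counts = {}
    for x, y in zip(qa.ravel(), qb.ravel()):
        counts[(x, y)] = counts.get((x, y), 0) + 1
    total = qa.size
    return -sum((c / total) * math.log2(c / total) for c in counts.values())


def mutual_information_oracle(f, a, b, levels: int = 256) -> float:
    def mi(x, y):
        return (entropy_oracle(x, levels) + entropy_oracle(y, levels)
                - joint_entropy_oracle(x, y, levels))

    return mi(a, f) + mi(b, f)


def psnr_oracle(f, a, b) -> float:
    m, n = f.shape
    mse_a = sum((a[i, j] - f[i, j]) ** 2 for i in range(m) for j in range(n)) / (m * n)
    mse_b = sum((b[i, j] - f[i, j]) ** 2 for i in range(m) for j in range(n)) / (m * n)
    mse = 0.5 * (mse_a + mse_b)
    r = float(f.max())
    return 10.0 * math.log10(r * r / mse)


def gaussian_window_oracle(size: int, sigma: float) -> np.ndarray:
    c = (size - 1) / 2.0
    w = np.array([[math.exp(-((i - c) ** 2 + (j - c) ** 2) / (2 * sigma ** 2))
                   for j in range(size)] for i in range(size)])
    return w / w.sum()


def ssim_windows_oracle(x: np.ndarray, y: np.ndarray, size: int = 11,
                        sigma: float = 1.5) -> float:
    """Mean windowed SSIM by explicit iteration over valid window positions."""
    win = gaussian_window_oracle(size, sigma)
    c1, c2 = 0.01 ** 2, 0.03 ** 2
    m, n = x.shape
    vals = []
    for i in range(m - size + 1):
        for j in range(n - size + 1):
            px = x[i : i + size, j : j + size]
            py = y[i : i + size, j : j + size]
            mx = float((win * px).sum())
            my = float((win * py).sum())
            vx = float((win * px * px).sum()) - mx * mx
            vy = float((win * py * py).sum()) - my * my
            cxy = float((win * px * py).sum()) - mx * my
            vals.append(((2 * mx * my + c1) * (2 * cxy + c2))
                        / ((mx * mx + my * my + c1) * (vx + vy + c2)))
    return float(np.mean(vals))


def qabf_oracle(f, a, b) -> float:
    """Per-pixel loop evaluation of the edge-preservation index."""
    sx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)

    def edges(img):
        m, n = img.shape
        g = np.zeros((m, n))
        alpha = np.zeros((m, n))
        for i in range(m):
            for j in range(n):
                gx = gy = 0.0
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ii = min(max(i + di, 0), m - 1)  # nearest-edge padding
                        jj = min(max(j + dj, 0), n - 1)
                        gx += sx[di + 1, dj + 1] * img[ii, jj]
                        gy += sx.T[di + 1, dj + 1] * img[ii, jj]
                g[i, j] = math.hypot(gx, gy)
                th = math.atan2(gy, gx)
                if th > math.pi / 2:
                    th -= math.pi
                if th <= -math.pi / 2:
                    th += math.pi
                alpha[i, j] = th
        return g, alpha

    gf, af = edges(f)
    ga, aa = edges(a)
    gb, ab = edges(b)

    def q(gs, As, i, j):
        if gs[i, j] > gf[i, j]:
            rel = gf[i, j] / gs[i, j]
        elif gf[i, j] > 0:
            rel = gs[i, j] / gf[i, j]
        else:
            rel = 0.0
        ang = 1.0 - abs(As[i, j] - af[i, j]) / (math.pi / 2.0)
        qg = 0.9994 / (1.0 + math.exp(-15.0 * (rel - 0.5)))
        qa_ = 0.9879 / (1.0 + math.exp(-22.0 * (ang - 0.8)))
        return qg * qa_

    num = den = 0.0
    m, n = f.shape
    for i in range(m):
        for j in range(n):
            num += q(ga, aa, i, j) * ga[i, j] + q(gb, ab, i, j) * gb[i, j]
            den += ga[i, j] + gb[i, j]
    return num / den if den else 0.0


def viff_oracle(f, a, b) -> float:
    """Window-by-window evaluation of the multi-scale VIF fusion measure."""
    sigma_n_sq, eps = 2.0, 1e-10
    imgs = [255.0 * np.asarray(x, dtype=float) for x in (f, a, b)]

    def stats(ref, dist, win):
        size = win.shape[0]
        m, n = ref.shape
        rows = []
        for i in range(m - size + 1):
            row = []
            for j in range(n - size + 1):
                pr = ref[i : i + size, j : j + size]
                pd = dist[i : i + size, j : j + size]
                mr = float((win * pr).sum())
                md = float((win * pd).sum())
                vr = max(float((win * pr * pr).sum()) - mr * mr, 0.0)
                vd = max(float((win * pd * pd).sum()) - md * md, 0.0)
                cv = float((win * pr * pd).sum()) - mr * md
                g = cv / (vr + eps)
                sv = vd - g * cv
                g = max(g, 0.0)
                sv = max(sv, eps)
                num = math.log10(1.0 + g * g * vr / (sv + sigma_n_sq))
                den = math.log10(1.0 + vr / sigma_n_sq)
                row.append((num, den))
            rows.append(row)
        return rows

    def decimate(img, win):
        size = win.shape[0]
        half = size // 2
        m, n = img.shape
        out = np.zeros((m, n))
        for i in range(m):
            for j in range(n):
                acc = 0.0
                for di in range(size):
                    for dj in range(size):
                        ii = i + di - half
                        jj = j + dj - half
                        ii = -ii - 1 if ii < 0 else (2 * m - ii - 1 if ii >= m else ii)
                        jj = -jj - 1 if jj < 0 else (2 * n - jj - 1 if jj >= n else jj)
                        acc += win[di, dj] * img[ii, jj]
                out[i, j] = acc
        return out[::2, ::2]

    ratios = []
    ff, fa, fb = imgs
    for scale in range(1, 5):
        n_win = 2 ** (4 - scale + 1) + 1
        win = gaussian_window_oracle(n_win, n_win / 5.0)
        if scale > 1:
            ff, fa, fb = decimate(ff, win), decimate(fa, win), decimate(fb, win)
        ta = stats(fa, ff, win)
        tb = stats(fb, ff, win)
        num = den = 0.0
        for ra, rb in zip(ta, tb):
            for (na, da), (nb, db) in zip(ra, rb):
                if da >= db:
                    num, den = num + na, den + da
                else:
                    num, den = num + nb, den + db
        ratios.append(num / den if den > 0 else 1.0)
    weights = np.array([0.5, 0.25, 0.15, 0.10])
    weights = weights / weights.sum()
    return float(np.dot(weights, ratios))


def paired_t_oracle(x, y):
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = d.size
    sd = d.std(ddof=1)
    t = d.mean() / (sd / math.sqrt(n))
    from scipy.stats import t as tdist

    p = 2.0 * tdist.sf(abs(t), df=n - 1)
    return t, p


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_phantom_pool():
    """Small phantom image pool for fast training smoke tests."""
    from res2fuse import generate_dataset

    data = generate_dataset(4, 64, seed=42)
    return [im for ct, mr, _ in data for im in (ct, mr)]
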