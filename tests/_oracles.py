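"""Independent brute-force oracles used by the test suite.

Everything here is written as plainly as possible (explicit loops, direct
formulas) and never calls into the package's own computation paths.
"""

from __future__ import annotations

import numpy as np


def guided_rule_loops(f: np.ndarray, R_next: np.ndarray) -> np.ndarray:
    """Elementwise guided-rectifier rule via explicit iteration."""
    out = np.zeros_like(R_next, dtype=float)
    it = np.nditer(f, flags=["multi_index"])
    for fv in it:
        idx = it.multi_index
        rv = R_next[idx]
        if fv > 0 and rv > 0:
            out[idx] = rv
    return out


def cut_value_loops(s: np.ndarray, k: int) -> float:
    """Eq.-style double sum: mean similarity across the cut at k (1-based)."""
    n = len(s)
    total = 0.0
    for i in range(1, k + 1):
        for j in range(k + 1, n + 1):
            total += s[i - 1, j - 1]
    return total / (k * (n - k))


def naive_ssim_gray(a: np.ndarray, b: np.ndarray, win: int = 7,
                    k1: float = 0.01, k2: float = 0.03,
                    data_range: float = 1.0) -> float:
    """Windowed SSIM on one channel: uniform window, sample (co)variance,
    mean over all fully contained windows."""
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    h, w = a.shape
    npix = win * win
    vals = []
    for i in range(h - win + 1):
        for j in range(w - win + 1):
            x = a[i : i + win, j : j + win].ravel()
            y = b[i : i + win, j : j + win].ravel()
            mx, my = x.mean(), y.mean()
            vx = ((x - mx) ** 2).sum() / (npix - 1)
            vy = ((y - my) ** 2).sum() / (npix - 1)
            cxy = ((x - mx) * (y - my)).sum() / (npix - 1)
            vals.append(
                ((2 * mx * my + c1) * (2 * cxy + c2))
                / ((mx * mx + my * my + c1) * (vx + vy + c2))
            )
    return float(np.mean(vals))


def naive_ssim_rgb(a: np.ndarray, b: np.ndarray, **kw) -> float:
    """Per-channel mean of the grayscale reference SSIM."""
    return float(np.mean([naive_ssim_gray(a[..., c], b[..., c], **kw)
                          for c in range(a.shape[2])]))


def random_ssim_like_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric matrix with unit diagonal and entries in [-1, 1]."""
    m = rng.uniform(-1, 1, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    return m


def two_block_matrix(n: int, boundary: int, within: float = 0.9,
                     cross: float = 0.2, noise_sd: float = 0.0,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Planted two-block similarity matrix with symmetric i.i.d. noise."""
    m = np.full((n, n), cross)
    m[:boundary, :boundary] = within
    m[boundary:, boundary:] = within
    if noise_sd > 0:
        assert rng is not None
        e = rng.normal(0, noise_sd, size=(n, n))
        m = m + (e + e.T) / 2
    np.fill_diagonal(m, 1.0)
    return m
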