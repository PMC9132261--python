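"""Pairwise SSIM between layer visualizations.

SSIM here is the standard windowed structural similarity index (Gaussian-free
uniform 7x7 window, k1=0.01, k2=0.03), computed per RGB channel and averaged
(``per_channel_mean``) so color differences between visualizations count, or
on the luminance channel alone (``luminance``).

The n x n matrix of pairwise SSIM values over the n layer visualizations of a
model on one image is the raw material of the cut-curve analysis: entry
(i, j) says how similar the features learned by layers i and j look in input
space.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["SSIMParams", "SSIMMatrix", "ssim_pair", "pairwise_ssim_matrix"]

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class SSIMParams:
    window_size: int = 7
    k1: float = 0.01
    k2: float = 0.03
    data_range: float = 1.0
    channel_mode: str = "per_channel_mean"  # or "luminance"

    def __post_init__(self) -> None:
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and >= 3")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1 and k2 must be positive")
        if self.data_range <= 0:
            raise ValueError("data_range must be positive")
        if self.channel_mode not in ("per_channel_mean", "luminance"):
            raise ValueError(f"unknown channel_mode {self.channel_mode!r}")


@dataclass
class SSIMMatrix:
    values: np.ndarray  # (n, n) symmetric, unit diagonal
    layer_count: int
    image_id: str = ""

    def validate(self, atol: float = 1e-12) -> None:
        v = self.values
        if v.shape != (self.layer_count, self.layer_count):
            raise ValueError("matrix shape inconsistent with layer_count")
        if not np.allclose(v, v.T, atol=atol, rtol=0):
            raise ValueError("SSIM matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=atol, rtol=0):
            raise ValueError("SSIM matrix diagonal is not 1")
        if v.min() < -1 - 1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("SSIM values outside [-1, 1]")

    # -- serialization (full float precision, so curves reproduce exactly) --
    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow([f"layer_{i + 1}" for i in range(self.layer_count)])
            for row in self.values:
                w.writerow([repr(float(x)) for x in row])

    @classmethod
    def from_csv(cls, path, image_id: str = "") -> "SSIMMatrix":
        with open(path) as fh:
            rows = list(csv.reader(fh))
        vals = np.array([[float(x) for x in r] for r in rows[1:]])
        return cls(vals, len(vals), image_id)

    def to_json(self, path) -> None:
        payload = {
            "image_id": self.image_id,
            "layer_count": self.layer_count,
            "values": [[float(x) for x in row] for row in self.values],
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SSIMMatrix":
        payload = json.loads(Path(path).read_text())
        return cls(np.array(payload["values"]), payload["layer_count"],
                   payload["image_id"])


def ssim_pair(a: np.ndarray, b: np.ndarray, params: SSIMParams | None = None) -> float:
    """Mean local SSIM between two images of the same shape, in [-1, 1]."""
    params = params or SSIMParams()
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if min(a.shape[0], a.shape[1]) < params.window_size:
        raise ValueError("image smaller than the SSIM window")
    kwargs = dict(
        win_size=params.window_size,
        K1=params.k1,
        K2=params.k2,
        data_range=params.data_range,
        gaussian_weights=False,
        use_sample_covariance=True,
    )
    if a.ndim == 2:
        return float(structural_similarity(a, b, **kwargs))
    if params.channel_mode == "luminance":
        return float(structural_similarity(a @ _LUMA, b @ _LUMA, **kwargs))
    vals = [structural_similarity(a[..., c], b[..., c], **kwargs)
            for c in range(a.shape[2])]
    return float(np.mean(vals))


def pairwise_ssim_matrix(visualizations, params: SSIMParams | None = None,
                         image_id: str = "") -> SSIMMatrix:
    """SSIM matrix over layer visualizations (upper triangle computed, then
    mirrored; diagonal set to 1 without computation)."""
    params = params or SSIMParams()
    if len(visualizations) < 2:
        raise ValueError("need at least 2 visualizations")
    imgs = [v.image if hasattr(v, "image") else np.asarray(v) for v in visualizations]
    shapes = {im.shape for im in imgs}
    if len(shapes) > 1:
        raise ValueError(f"mixed visualization shapes: {sorted(shapes)}")
    n = len(imgs)
    s = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s[i, j] = s[j, i] = ssim_pair(imgs[i], imgs[j], params)
    return SSIMMatrix(s, n, image_id)
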