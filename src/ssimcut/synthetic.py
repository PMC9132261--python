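"""Synthetic plant-like image datasets with controllable confounds.

Each image is a top-down "rosette": a superposition of rotated elliptical
lobes around a center, composited onto a soil-colored background. The class
signal is carried by the lobe count and by the hue band of the foreground
green — a deliberately strong cue so that even a shallow CNN trained for a
single epoch separates classes above chance.

Background confounds emulate the structure of field/greenhouse datasets:

* ``lighting_patches`` — a seeded low-frequency multiplicative lighting field
  whose amplitude is ``lighting_variability``; the irregular bright patches a
  high-capacity model can latch onto instead of the plant.
* ``grainy`` — i.i.d. speckle added to background pixels only, mimicking
  close-up leaf photographs with grainy backdrops.

Ground-truth foreground masks are kept on the dataset so segmentation and
visualization-locality checks have an exact oracle.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate",
    "segment_green",
    "export",
    "load_dataset",
]

_SOIL = np.array([0.45, 0.36, 0.28])
# per-class foreground hue bands (yellow-green, green, blue-green, then cycled)
_GREENS = [
    np.array([0.30, 0.55, 0.10]),
    np.array([0.10, 0.55, 0.15]),
    np.array([0.10, 0.50, 0.30]),
]


@dataclass
class SyntheticConfig:
    class_count: int = 3
    images_per_class: int = 100
    image_size: int = 64
    background_mode: str = "lighting_patches"  # {"uniform","lighting_patches","grainy"}
    lighting_variability: float = 0.25
    base_lobes: int = 3  # class c gets base_lobes + c lobes
    lobe_size: tuple[float, float] = (0.16, 0.24)  # semi-major axis, fraction of image
    hue_jitter: float = 0.03
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_count < 2:
            raise ValueError("class_count must be >= 2")
        if self.images_per_class < 10:
            raise ValueError("images_per_class must be >= 10")
        if not 0.0 <= self.lighting_variability <= 1.0:
            raise ValueError("lighting_variability must be in [0, 1]")
        if self.background_mode not in ("uniform", "lighting_patches", "grainy"):
            raise ValueError(f"unknown background_mode {self.background_mode!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lobe_size"] = list(d["lobe_size"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "lobe_size" in d:
            d["lobe_size"] = tuple(d["lobe_size"])
        return cls(**d)


@dataclass
class SyntheticDataset:
    images: np.ndarray  # (N, H, W, 3) float in [0, 1]
    labels: np.ndarray  # (N,) int class ids
    split: dict  # {"train"|"test"|"validation": index array}
    config: SyntheticConfig | None = None
    masks: np.ndarray | None = None  # (N, H, W) bool ground-truth foreground
    filenames: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.images)


def _lighting_field(size: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    coarse = rng.normal(size=(5, 5))
    f = ndimage.zoom(coarse, size / 5.0, order=3)[:size, :size]
    f = f / (np.abs(f).max() + 1e-12)
    return 1.0 + amplitude * f


def _render_image(cls: int, size: int, cfg: SyntheticConfig,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cx = size / 2 + rng.uniform(-0.08, 0.08) * size
    cy = size / 2 + rng.uniform(-0.08, 0.08) * size

    n_lobes = cfg.base_lobes + cls
    a_frac = rng.uniform(*cfg.lobe_size)
    a = a_frac * size
    b = 0.4 * a
    r0 = 0.55 * a  # lobe center distance from rosette center
    phase = rng.uniform(0, 2 * np.pi)

    # q(x) = min over lobes of the ellipse quadratic form; q < 1 is inside
    q = np.full((size, size), np.inf)
    for l in range(n_lobes):
        th = phase + 2 * np.pi * l / n_lobes + rng.normal(0, 0.08)
        lx = cx + r0 * np.cos(th)
        ly = cy + r0 * np.sin(th)
        u = (xx - lx) * np.cos(th) + (yy - ly) * np.sin(th)
        v = -(xx - lx) * np.sin(th) + (yy - ly) * np.cos(th)
        al = a * rng.uniform(0.85, 1.15)
        q = np.minimum(q, (u / al) ** 2 + (v / b) ** 2)

    alpha = np.clip((1.0 - q) / 0.15, 0.0, 1.0)
    mask = alpha > 0.5

    base = _GREENS[cls % len(_GREENS)]
    fg_color = np.clip(base + rng.uniform(-cfg.hue_jitter, cfg.hue_jitter, size=3), 0, 1)
    shading = 0.8 + 0.4 * np.clip(1.0 - q, 0.0, 1.0)
    fg = shading[:, :, None] * fg_color[None, None, :]

    bg = np.broadcast_to(_SOIL, (size, size, 3)).copy()
    if cfg.background_mode == "lighting_patches":
        bg = bg * _lighting_field(size, cfg.lighting_variability, rng)[:, :, None]
    elif cfg.background_mode == "grainy":
        bg = bg + rng.normal(0, 0.04, size=(size, size, 1))

    img = bg * (1.0 - alpha[:, :, None]) + fg * alpha[:, :, None]
    if cfg.noise_sd > 0:
        img = img + rng.normal(0, cfg.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0), mask


def _stratified_split(labels: np.ndarray, rng: np.random.Generator) -> dict:
    """80/10/10 split, stratified by class, proportions within one image."""
    train, test, val = [], [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(len(idx))]
        n = len(idx)
        n_te = max(1, round(0.1 * n))
        n_va = max(1, round(0.1 * n))
        test.extend(idx[:n_te])
        val.extend(idx[n_te : n_te + n_va])
        train.extend(idx[n_te + n_va :])
    return {
        "train": np.sort(np.array(train)),
        "test": np.sort(np.array(test)),
        "validation": np.sort(np.array(val)),
    }


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a labelled, split dataset; byte-identical for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    n = config.class_count * config.images_per_class
    size = config.image_size
    images = np.empty((n, size, size, 3), dtype=np.float32)
    masks = np.empty((n, size, size), dtype=bool)
    labels = np.repeat(np.arange(config.class_count), config.images_per_class)
    filenames = []
    for i, cls in enumerate(labels):
        img, m = _render_image(int(cls), size, config, rng)
        images[i] = img
        masks[i] = m
        k = i % config.images_per_class
        filenames.append(f"class_{cls}/img_{k:04d}.png")
    split = _stratified_split(labels, rng)
    return SyntheticDataset(images, labels, split, config, masks, filenames)


def segment_green(image: np.ndarray, margin: float = 0.02) -> np.ndarray:
    """Keep green-dominant pixels, blacken everything else.

    A pixel is green when its green channel exceeds both red and blue by
    ``margin`` (on the [0, 1] scale).
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB image, got shape {image.shape}")
    r, g, b = image[..., 0], image[..., 1], image[..., 2]
    keep = (g > r + margin) & (g > b + margin)
    return image * keep[:, :, None]


def export(dataset: SyntheticDataset, directory) -> list[Path]:
    """Write PNGs under ``class_<id>/`` plus labels.csv, split.csv and a
    config echo; returns the written paths. Round-trips at 8-bit precision."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    part_of = {}
    for name, idx in dataset.split.items():
        for i in idx:
            part_of[int(i)] = name
    for i, fname in enumerate(dataset.filenames):
        path = directory / fname
        path.parent.mkdir(exist_ok=True)
        arr = np.round(dataset.images[i] * 255).astype(np.uint8)
        Image.fromarray(arr).save(path)
        written.append(path)
    with open(directory / "labels.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["filename", "class"])
        for fname, lbl in zip(dataset.filenames, dataset.labels):
            w.writerow([fname, int(lbl)])
    with open(directory / "split.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["filename", "partition"])
        for i, fname in enumerate(dataset.filenames):
            w.writerow([fname, part_of[i]])
    written += [directory / "labels.csv", directory / "split.csv"]
    if dataset.config is not None:
        with open(directory / "config.json", "w") as fh:
            json.dump(dataset.config.to_dict(), fh, indent=2, sort_keys=True)
    return written


def load_dataset(directory) -> SyntheticDataset:
    """Re-import a dataset written by :func:`export` (masks are not stored)."""
    directory = Path(directory)
    with open(directory / "labels.csv") as fh:
        rows = list(csv.DictReader(fh))
    with open(directory / "split.csv") as fh:
        parts = {r["filename"]: r["partition"] for r in csv.DictReader(fh)}
    images, labels, filenames = [], [], []
    split: dict[str, list[int]] = {"train": [], "test": [], "validation": []}
    for i, row in enumerate(rows):
        fname = row["filename"]
        arr = np.asarray(Image.open(directory / fname), dtype=np.float32) / 255.0
        images.append(arr)
        labels.append(int(row["class"]))
        filenames.append(fname)
        split[parts[fname]].append(i)
    config = None
    cfg_path = directory / "config.json"
    if cfg_path.exists():
        config = SyntheticConfig.from_dict(json.loads(cfg_path.read_text()))
    return SyntheticDataset(
        np.stack(images),
        np.array(labels),
        {k: np.array(v) for k, v in split.items()},
        config,
        None,
        filenames,
    )
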