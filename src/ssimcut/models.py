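"""Model factory for the two desk-scale CNN families the analysis targets.

Two families mirror the usual designs in plant-classification work:

* ``shallow`` — a plain stack of 3x3 conv/batch-norm/ReLU layers (no skip
  connections), parameterized purely by the number of convolutional layers
  (>= 2). Width grows 8 -> 16 -> 32 filters, with 2x2 max-pooling after the
  2nd, 4th and 6th convolution so the 64x64 default input ends at 8x8 before
  global pooling.
* ``residual`` — a stem convolution followed by ``block_count - 1`` residual
  block groups (each: conv-BN-ReLU-conv-BN, identity/1x1-projection shortcut,
  ReLU after the merge), emulating block-truncated residual classifiers. The
  1x1 projection convolutions on shortcuts are not counted toward depth by
  default.

The classifier head is global average pooling into a fully connected layer;
softmax is applied inside the cross-entropy loss and at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .nn.network import Network
from .nn.ops import Add, BatchNorm, Conv2D, Dense, GlobalAvgPool, MaxPool2D, ReLU

__all__ = ["ModelSpec", "build_model"]

_SHALLOW_WIDTHS = (8, 8, 16, 16, 32, 32)  # then 32 for any deeper conv
_RESIDUAL_GROUP_WIDTHS = (16, 16, 32, 32)  # widths for groups 2..5


@dataclass
class ModelSpec:
    """Declarative description of a CNN the harness can build."""

    family: str = "shallow"  # {"shallow", "residual"}
    conv_layers: int = 6  # shallow family depth
    block_count: int = 2  # residual family: number of block groups incl. stem
    input_size: int = 64
    class_count: int = 3
    seed: int = 0
    count_shortcut_convs: bool = False

    def __post_init__(self) -> None:
        if self.family not in ("shallow", "residual"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.family == "shallow" and self.conv_layers < 2:
            raise ValueError("shallow family needs >= 2 conv layers")
        if self.family == "residual" and self.block_count not in (2, 3, 4, 5):
            raise ValueError("residual block_count must be in {2,3,4,5}")
        if self.class_count < 2:
            raise ValueError("class_count must be >= 2")
        if self.input_size < 16:
            raise ValueError("input_size must be >= 16")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)


def _shallow_width(i: int) -> int:
    return _SHALLOW_WIDTHS[i] if i < len(_SHALLOW_WIDTHS) else 32


def build_model(spec: ModelSpec) -> Network:
    """Build a deterministic, seeded network from ``spec``.

    The same spec always yields bit-identical initial weights.
    """
    rng = np.random.default_rng(spec.seed)
    net = Network(input_shape=(spec.input_size, spec.input_size, 3))
    c = 3
    size = spec.input_size

    if spec.family == "shallow":
        n_pools = 0
        for i in range(spec.conv_layers):
            w = _shallow_width(i)
            net.add(Conv2D(c, w, rng=rng), name=f"conv{i + 1}", included_conv=True)
            net.add(BatchNorm(w), name=f"bn{i + 1}")
            net.add(ReLU(), name=f"relu{i + 1}")
            c = w
            # pool after every second conv while the map is still large
            if (i + 1) % 2 == 0 and n_pools < 3 and size > 8:
                net.add(MaxPool2D(), name=f"pool{n_pools + 1}")
                size //= 2
                n_pools += 1
    else:
        # stem (group 1)
        net.add(Conv2D(c, 8, rng=rng), name="stem_conv", included_conv=True)
        net.add(BatchNorm(8), name="stem_bn")
        net.add(ReLU(), name="stem_relu")
        stem_pool = net.add(MaxPool2D(), name="stem_pool")
        size //= 2
        c = 8
        prev = stem_pool
        for g in range(spec.block_count - 1):
            w = _RESIDUAL_GROUP_WIDTHS[g]
            n1 = net.add(Conv2D(c, w, rng=rng), inputs=prev,
                         name=f"g{g + 2}_conv1", included_conv=True)
            n1b = net.add(BatchNorm(w), inputs=n1, name=f"g{g + 2}_bn1")
            n2 = net.add(ReLU(), inputs=n1b, name=f"g{g + 2}_relu1")
            n3 = net.add(Conv2D(w, w, rng=rng), inputs=n2,
                         name=f"g{g + 2}_conv2", included_conv=True)
            n3 = net.add(BatchNorm(w), inputs=n3, name=f"g{g + 2}_bn2")
            if c != w:
                shortcut = net.add(
                    Conv2D(c, w, ksize=1, rng=rng), inputs=prev,
                    name=f"g{g + 2}_proj",
                    included_conv=spec.count_shortcut_convs,
                )
            else:
                shortcut = prev
            n4 = net.add(Add(), inputs=(n3, shortcut), name=f"g{g + 2}_add")
            n5 = net.add(ReLU(), inputs=n4, name=f"g{g + 2}_relu2")
            prev = n5
            c = w
            if size > 8:
                prev = net.add(MaxPool2D(), inputs=prev, name=f"g{g + 2}_pool")
                size //= 2

    net.add(GlobalAvgPool(), name="gap")
    net.add(Dense(c, spec.class_count, rng=rng), name="head")
    return net
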