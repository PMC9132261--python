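"""Guided backpropagation (GBP) visualizations of convolutional layers.

GBP renders, for each convolutional layer, an input-space image of the
features that activate it. The forward pass is the ordinary one; at every
rectifier the backward pass keeps only positive signal flowing through
positive activations:

    R_l = (f_l > 0) * (R_{l+1} > 0) * R_{l+1}

The backward pass is seeded at the chosen layer's rectified output — by
default with an all-ones signal, visualizing the layer as a whole; a
``max_channel`` mode seeds only the most strongly activated feature map.

Zero input-space gradient renders as uniform mid-gray (0.5 per channel):
gray regions of a visualization are regions of the image that do not drive
the layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.network import Network
from .nn.ops import BatchNorm, ReLU

__all__ = [
    "GuidedGradient",
    "LayerVisualization",
    "guided_relu_backward",
    "render_gradient",
    "layer_visualization",
    "all_layer_visualizations",
]

#: rendering constants: gradient / (std + EPS) * GAIN + 0.5, clipped to [0, 1]
RENDER_GAIN = 0.1
RENDER_EPS = 1e-8


@dataclass
class GuidedGradient:
    layer_index: int  # 1-based over included conv layers
    R: np.ndarray  # backward signal at that layer, same shape as f_l


@dataclass
class LayerVisualization:
    layer_index: int
    image: np.ndarray  # (H, W, 3) in [0, 1]
    raw_gradient: np.ndarray  # unnormalized input-space guided gradient


def guided_relu_backward(f: np.ndarray, R_next: np.ndarray) -> np.ndarray:
    """Apply the guided rectifier rule elementwise.

    Returns R with R[x] = R_next[x] where f[x] > 0 and R_next[x] > 0, else 0.
    """
    f = np.asarray(f)
    R_next = np.asarray(R_next)
    if f.shape != R_next.shape:
        raise ValueError(f"shape mismatch: f {f.shape} vs R {R_next.shape}")
    return np.where((f > 0) & (R_next > 0), R_next, 0.0)


def render_gradient(raw_gradient: np.ndarray, layer_index: int | None = None) -> np.ndarray:
    """Map an input-space gradient to an RGB image centered at mid-gray.

    The gradient is scaled by its global standard deviation, so the mapping
    is monotone in gradient magnitude; zero gradient gives uniform 0.5.
    """
    g = np.asarray(raw_gradient, dtype=np.float64)
    if not np.isfinite(g).all():
        where = f" at layer {layer_index}" if layer_index is not None else ""
        raise ValueError(f"non-finite gradient{where}")
    img = g / (g.std() + RENDER_EPS) * RENDER_GAIN + 0.5
    return np.clip(img, 0.0, 1.0)


def _seed_node(net: Network, layer_index: int) -> int:
    """Node index of the rectified output of included conv #layer_index.

    If the convolution is not followed by a rectifier, the convolution's own
    output is the seed point.
    """
    convs = net.conv_node_indices
    if not 1 <= layer_index <= len(convs):
        raise IndexError(
            f"layer_index {layer_index} out of range 1..{len(convs)}"
        )
    node = convs[layer_index - 1]
    # walk forward through unary passthroughs (batch norm) to the rectifier
    cur = node
    while cur < len(net.nodes) and net.nodes[cur].inputs == (cur,):
        nxt_op = net.nodes[cur].op
        if isinstance(nxt_op, ReLU):
            return cur + 1
        if isinstance(nxt_op, BatchNorm):
            cur += 1
            continue
        break
    return node


def _visualize_from_outs(net: Network, outs: list[np.ndarray], layer_index: int,
                         seed_mode: str) -> LayerVisualization:
    node = _seed_node(net, layer_index)
    act = outs[node]
    if seed_mode == "ones":
        seed = np.ones_like(act)
    elif seed_mode == "max_channel":
        ch = int(np.argmax(np.abs(act).sum(axis=(0, 1, 2))))
        seed = np.zeros_like(act)
        seed[..., ch] = 1.0
    else:
        raise ValueError(f"unknown seed_mode {seed_mode!r}")
    grad = net.backward(outs, node, seed, guided=True)[0]
    return LayerVisualization(layer_index, render_gradient(grad, layer_index), grad)


def layer_visualization(net: Network, image: np.ndarray, layer_index: int,
                        seed_mode: str = "ones") -> LayerVisualization:
    """GBP visualization of one convolutional layer on one image."""
    convs = net.conv_node_indices
    if not 1 <= layer_index <= len(convs):
        raise IndexError(f"layer_index {layer_index} out of range 1..{len(convs)}")
    outs = net.forward(np.asarray(image, dtype=np.float32),
                       upto=_seed_node(net, layer_index))
    # pad the output list so node indexing stays valid
    return _visualize_from_outs(net, outs, layer_index, seed_mode)


def all_layer_visualizations(net: Network, image: np.ndarray,
                             seed_mode: str = "ones") -> list[LayerVisualization]:
    """GBP visualizations for every included conv layer, forward order.

    A single forward pass is shared across all layers; only the backward
    passes are per-layer.
    """
    n = net.n_conv_layers
    if n < 2:
        raise ValueError("cut-curve analysis needs a model with >= 2 conv layers")
    outs = net.forward(np.asarray(image, dtype=np.float32))
    return [_visualize_from_outs(net, outs, k, seed_mode) for k in range(1, n + 1)]
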