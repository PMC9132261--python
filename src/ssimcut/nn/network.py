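"""A small layer-graph container supporting plain and residual CNNs.

The network is a topologically ordered list of nodes; each node wraps one op
from :mod:`ssimcut.nn.ops` and names the node(s) it consumes. Node 0 is the
input image batch. This explicit-graph design exists so that the backward pass
can be *seeded at any intermediate node* — the operation guided
backpropagation needs — rather than only at the loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ops import Add, Conv2D, Dense, GlobalAvgPool, MaxPool2D, Op, ReLU

__all__ = ["Node", "Network"]


@dataclass
class Node:
    op: Op
    inputs: tuple[int, ...]
    name: str = ""
    #: marks convolutions counted toward model depth (shortcut 1x1 projections
    #: are excluded by default)
    included_conv: bool = False


@dataclass
class Network:
    nodes: list[Node] = field(default_factory=list)
    input_shape: tuple[int, int, int] = (64, 64, 3)  # H, W, C

    # -- construction -----------------------------------------------------
    def add(self, op: Op, inputs: int | tuple[int, ...] | None = None, *,
            name: str = "", included_conv: bool = False) -> int:
        """Append a node consuming ``inputs`` (default: previous node) and
        return its index. Index 0 refers to the input image."""
        if inputs is None:
            inputs = (len(self.nodes),)  # previous node (input=0 when empty)
        elif isinstance(inputs, int):
            inputs = (inputs,)
        self.nodes.append(Node(op, tuple(inputs), name=name, included_conv=included_conv))
        return len(self.nodes)  # node indices are 1-based; 0 is the input

    # -- introspection ----------------------------------------------------
    @property
    def conv_node_indices(self) -> list[int]:
        """1-based node indices of included convolutions, forward order."""
        return [i + 1 for i, nd in enumerate(self.nodes) if nd.included_conv]

    @property
    def n_conv_layers(self) -> int:
        return len(self.conv_node_indices)

    def parameters(self):
        """Yield (key, op, param_name) triples for all trainable arrays."""
        for i, nd in enumerate(self.nodes):
            for pname in nd.op.params:
                yield f"n{i}.{pname}", nd.op, pname

    # -- execution ---------------------------------------------------------
    def forward(self, x: np.ndarray, upto: int | None = None,
                train: bool = False) -> list[np.ndarray]:
        """Run the graph, returning per-node outputs (index 0 = input).

        ``upto`` stops execution after that node (1-based), which is all the
        guided-backprop path needs. ``train`` switches batch-norm nodes to
        batch statistics.
        """
        for nd in self.nodes:
            if hasattr(nd.op, "training"):
                nd.op.training = train
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != self.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match model input {self.input_shape}"
            )
        outs: list[np.ndarray] = [x]
        last = len(self.nodes) if upto is None else upto
        for idx in range(1, last + 1):
            nd = self.nodes[idx - 1]
            args = [outs[j] for j in nd.inputs]
            outs.append(nd.op.forward(*args))
        return outs

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[-1]

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.logits(x), axis=1)

    def backward(self, outs: list[np.ndarray], seed_node: int,
                 seed: np.ndarray, guided: bool = False) -> np.ndarray:
        """Backpropagate ``seed`` from ``seed_node`` (1-based) to the input.

        Returns the gradient with respect to the input batch. In guided mode
        every rectifier applies the guided rule; parametric ops still record
        their parameter gradients (harmless for visualization, needed for
        training where seed_node is the head).
        """
        grads: dict[int, np.ndarray] = {seed_node: seed}
        for idx in range(seed_node, 0, -1):
            g = grads.pop(idx, None)
            if g is None:
                continue
            nd = self.nodes[idx - 1]
            gin = nd.op.backward(g, guided=guided)
            if nd.op.arity == 1:
                gin = (gin,)
            for j, gj in zip(nd.inputs, gin):
                if j in grads:
                    grads[j] = grads[j] + gj
                else:
                    grads[j] = gj
        return grads.get(0, np.zeros_like(outs[0]))

    # -- persistence --------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {key: op.params[p] for key, op, p in self.parameters()}
        for i, nd in enumerate(self.nodes):
            for bname, buf in nd.op.buffers.items():
                state[f"n{i}.buffer.{bname}"] = buf
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, op, p in self.parameters():
            if key not in state:
                raise KeyError(f"missing parameter {key} in checkpoint")
            if state[key].shape != op.params[p].shape:
                raise ValueError(f"shape mismatch for {key}")
            op.params[p] = np.asarray(state[key])
        for i, nd in enumerate(self.nodes):
            for bname in nd.op.buffers:
                key = f"n{i}.buffer.{bname}"
                if key not in state:
                    raise KeyError(f"missing buffer {key} in checkpoint")
                nd.op.buffers[bname] = np.asarray(state[key])

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})
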