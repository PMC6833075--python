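"""Assemble trainable networks from declarative architecture specs.

``build_network`` walks an ordered layer list (duck-typed: items expose
``kind``, ``n``, ``size``, ``activation``, ``dropout_rate``) and emits the
corresponding trainable layers with shapes inferred from the input shape.

Activation placement: a convolution or dense layer declared with an ELU
activation that is immediately followed by batch normalisation is emitted as
conv -> batch-norm -> ELU (normalise the linear response, then activate);
otherwise the activation follows the layer directly.  Softmax/linear output
activations are not emitted as layers - the softmax is fused with the
cross-entropy loss during training and applied explicitly at prediction.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm,
    Conv1D,
    Conv2D,
    Dense,
    Dropout,
    ELU,
    Flatten,
    Layer,
    MaxPool,
)

__all__ = ["Sequential", "build_network", "infer_shapes"]


class Sequential:
    """A plain layer stack with explicit forward/backward passes."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers
        if layers and isinstance(layers[0], (Conv1D, Conv2D)):
            layers[0].is_input_layer = True  # its input gradient is never used

    def forward(self, x, training: bool = False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]


def _as_tuple(size) -> tuple[int, ...]:
    if size is None:
        return ()
    if np.isscalar(size):
        return (int(size),)
    return tuple(int(s) for s in size)


def infer_shapes(layers, input_shape: tuple[int, ...]):
    """Yield (layer_spec, input_shape, output_shape) walking the stack.

    Shapes exclude the batch axis: ``(L, C)`` for 1D, ``(H, L, C)`` for 2D,
    ``(F,)`` after flattening.  Convolutions keep the time axis ('same'
    padding) and reduce a leading row axis by ``kh - 1`` ('valid').
    """
    shape = tuple(int(s) for s in input_shape)
    for spec in layers:
        kind = spec.kind
        if kind == "conv1d":
            out = (shape[0], int(spec.n))
        elif kind == "conv2d":
            kh = _as_tuple(spec.size)[0]
            out = (shape[0] - kh + 1, shape[1], int(spec.n))
        elif kind == "batch_norm":
            out = shape
        elif kind == "max_pool":
            out = shape[:-2] + (shape[-2] // 2, shape[-1])
        elif kind == "dropout":
            out = shape
        elif kind == "flatten":
            out = (int(np.prod(shape)),)
        elif kind == "dense":
            out = (int(spec.n),)
        else:
            raise ValueError(f"unknown layer kind {kind!r}")
        yield spec, shape, out
        shape = out


def build_network(
    layers, input_shape: tuple[int, ...], rng, dtype=np.float32
) -> Sequential:
    built: list[Layer] = []
    specs = list(infer_shapes(layers, input_shape))
    for i, (spec, shape_in, _shape_out) in enumerate(specs):
        kind = spec.kind
        next_kind = specs[i + 1][0].kind if i + 1 < len(specs) else None
        if kind == "conv1d":
            built.append(Conv1D(_as_tuple(spec.size)[0], shape_in[-1], int(spec.n), rng, dtype))
        elif kind == "conv2d":
            built.append(Conv2D(_as_tuple(spec.size), shape_in[-1], int(spec.n), rng, dtype))
        elif kind == "batch_norm":
            built.append(BatchNorm(shape_in[-1], dtype=dtype))
        elif kind == "max_pool":
            built.append(MaxPool(2))
        elif kind == "dropout":
            built.append(Dropout(float(spec.dropout_rate)))
        elif kind == "flatten":
            built.append(Flatten())
        elif kind == "dense":
            built.append(Dense(shape_in[0], int(spec.n), rng, dtype))
        if kind in ("conv1d", "conv2d", "dense") and spec.activation == "elu":
            if next_kind == "batch_norm":
                pass  # ELU emitted right after the batch-norm layer below
            else:
                built.append(ELU())
        if kind == "batch_norm":
            prev = specs[i - 1][0] if i > 0 else None
            if prev is not None and prev.kind in ("conv1d", "conv2d", "dense") and prev.activation == "elu":
                built.append(ELU())
    return Sequential(built)
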