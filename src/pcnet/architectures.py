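"""Network constructors used throughout the experiments.

Three families:

* ``make_mlp3`` — 3-layer fully connected classifier, 800 hidden units by
  default, ReLU on the hidden layers, optional dropout (used for the
  MNIST-scale incremental and long-tailed runs).
* ``make_alexnet3`` — simplified AlexNet: three convolution blocks with
  64/128/256 channels followed by a single affine classifier (used for the
  CIFAR-scale incremental runs).
* ``make_protonet4`` — the standard prototypical-network encoder: four
  identical convolution blocks (batch norm + ReLU + 2x2 max-pool), no
  classifier head; the flattened block-4 output is the embedding.

Kernel size (3x3, stride 1, same padding) and 2x2 pooling are defaults and
configurable; channel plans and widths follow the experimental protocol the
package reproduces.
"""

from __future__ import annotations

import math

from .errors import ConfigurationError
from .network import LayerSpec, NetworkSpec


def make_mlp3(input_dim=784, hidden_width=800, classes=10,
              dropout_rate=0.0) -> NetworkSpec:
    """3 affine layers: input -> hidden -> hidden -> classes."""
    if input_dim <= 0 or hidden_width <= 0 or classes <= 0:
        raise ConfigurationError("input_dim, hidden_width and classes must be positive")
    return NetworkSpec((
        LayerSpec("affine", (input_dim,), (hidden_width,), "relu", dropout_rate),
        LayerSpec("affine", (hidden_width,), (hidden_width,), "relu", dropout_rate),
        LayerSpec("affine", (hidden_width,), (classes,), "identity", 0.0),
    ))


def _conv_chain(input_shape, channels, kernel_size, pool_size, batchnorm):
    c, h, w = input_shape
    layers = []
    for c_out in channels:
        if h < pool_size or w < pool_size:
            raise ConfigurationError(
                f"spatial size {h}x{w} too small for {pool_size}x{pool_size} pooling")
        h2, w2 = h // pool_size, w // pool_size
        layers.append(LayerSpec("conv_block", (c, h, w), (c_out, h2, w2),
                                "relu", 0.0, batchnorm, kernel_size, pool_size))
        c, h, w = c_out, h2, w2
    return layers, (c, h, w)


def make_alexnet3(input_shape=(3, 32, 32), classes=10,
                  channels=(64, 128, 256), kernel_size=3, pool_size=2,
                  batchnorm=False) -> NetworkSpec:
    """Three conv blocks (64/128/256 channels) plus an affine classifier."""
    if tuple(channels) != (64, 128, 256):
        raise ConfigurationError("the simplified AlexNet channel plan is (64, 128, 256)")
    if classes <= 0:
        raise ConfigurationError("classes must be positive")
    layers, feat = _conv_chain(input_shape, channels, kernel_size, pool_size,
                               batchnorm)
    layers.append(LayerSpec("affine", feat, (classes,), "identity"))
    return NetworkSpec(tuple(layers))


def make_protonet4(input_shape=(1, 28, 28), channels=64, kernel_size=3,
                   pool_size=2) -> NetworkSpec:
    """Four identical conv blocks with batch norm; output is the embedding.

    With a 28x28 input and 64 channels the four 2x poolings leave a 1x1
    map, i.e. a 64-dimensional embedding.
    """
    if channels <= 0:
        raise ConfigurationError("channels must be positive")
    layers, _ = _conv_chain(input_shape, (channels,) * 4, kernel_size,
                            pool_size, batchnorm=True)
    return NetworkSpec(tuple(layers))


def embed_dim(spec: NetworkSpec) -> int:
    """Flattened size of the network's final output."""
    return math.prod(spec.out_shape)


def parameter_count(spec: NetworkSpec) -> int:
    from .network import param_shapes
    total = 0
    for shapes in param_shapes(spec):
        for k, s in shapes.items():
            if k in ("running_mean", "running_var"):
                continue
            total += math.prod(s)
    return total
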