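"""Network specification and parameter containers.

A network is a strict chain of layers: layer ``i`` consumes the output of
layer ``i-1`` (no branching, no skip connections).  Two transform kinds are
supported:

``affine``
    Flatten -> W x + b -> nonlinearity -> (optional dropout).

``conv_block``
    3x3 same-padding convolution -> (optional batch norm) -> nonlinearity ->
    max pooling.  The whole block is a single predictive-coding layer with a
    single error node at its output.

Parameters live in a plain ``list[dict[str, ndarray]]`` (one dict per layer)
so they can be checkpointed to a ``.npz`` archive bit-exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError, StructureError

NONLINEARITIES = ("relu", "identity")
TRANSFORM_KINDS = ("affine", "conv_block")


@dataclass(frozen=True)
class LayerSpec:
    """Description of one predictive-coding layer.

    ``in_shape``/``out_shape`` exclude the batch dimension.  Convolutional
    shapes are channels-first ``(C, H, W)``.
    """

    transform_kind: str
    in_shape: tuple
    out_shape: tuple
    nonlinearity: str = "relu"
    dropout_rate: float = 0.0
    has_batchnorm: bool = False
    kernel_size: int = 3
    pool_size: int = 2

    def __post_init__(self):
        if self.transform_kind not in TRANSFORM_KINDS:
            raise ConfigurationError(
                f"unknown transform kind {self.transform_kind!r}")
        if self.nonlinearity not in NONLINEARITIES:
            raise ConfigurationError(
                f"unknown nonlinearity {self.nonlinearity!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        object.__setattr__(self, "in_shape", tuple(self.in_shape))
        object.__setattr__(self, "out_shape", tuple(self.out_shape))


@dataclass(frozen=True)
class NetworkSpec:
    """Ordered chain of :class:`LayerSpec`."""

    layers: tuple = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "layers", tuple(self.layers))
        if not self.layers:
            raise ConfigurationError("NetworkSpec needs at least one layer")
        for i in range(1, len(self.layers)):
            prev, cur = self.layers[i - 1], self.layers[i]
            if cur.transform_kind == "affine":
                # affine layers flatten their input
                if math.prod(cur.in_shape) != math.prod(prev.out_shape):
                    raise StructureError(
                        f"layer {i}: input size {cur.in_shape} does not match "
                        f"layer {i - 1} output {prev.out_shape}")
            elif cur.in_shape != prev.out_shape:
                raise StructureError(
                    f"layer {i}: input shape {cur.in_shape} does not match "
                    f"layer {i - 1} output {prev.out_shape}")

    def __len__(self):
        return len(self.layers)

    @property
    def in_shape(self):
        return self.layers[0].in_shape

    @property
    def out_shape(self):
        return self.layers[-1].out_shape

    def to_dict(self) -> dict:
        return {"layers": [asdict(l) for l in self.layers]}

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(tuple(LayerSpec(**ld) for ld in d["layers"]))

    def save(self, path):
        """Write the spec as JSON or YAML, chosen by file extension."""
        path = Path(path)
        d = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(d))
        else:
            path.write_text(json.dumps(d, indent=2))

    @classmethod
    def load(cls, path) -> "NetworkSpec":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# parameters

def _fan_in(layer: LayerSpec) -> int:
    if layer.transform_kind == "affine":
        return math.prod(layer.in_shape)
    c_in = layer.in_shape[0]
    return c_in * layer.kernel_size ** 2


def init_params(spec: NetworkSpec, seed: int = 0) -> list:
    """Scaled uniform fan-in initialization, U(-1/sqrt(fan_in), +1/sqrt(fan_in))."""
    rng = np.random.default_rng(seed)
    params = []
    for layer in spec.layers:
        a = 1.0 / math.sqrt(_fan_in(layer))
        p = {}
        if layer.transform_kind == "affine":
            n_in = math.prod(layer.in_shape)
            n_out = math.prod(layer.out_shape)
            p["W"] = rng.uniform(-a, a, size=(n_out, n_in))
            p["b"] = rng.uniform(-a, a, size=(n_out,))
        else:
            c_in = layer.in_shape[0]
            c_out = layer.out_shape[0]
            k = layer.kernel_size
            p["W"] = rng.uniform(-a, a, size=(c_out, c_in, k, k))
            p["b"] = rng.uniform(-a, a, size=(c_out,))
            if layer.has_batchnorm:
                p["gamma"] = np.ones(c_out)
                p["beta"] = np.zeros(c_out)
                p["running_mean"] = np.zeros(c_out)
                p["running_var"] = np.ones(c_out)
        params.append(p)
    return params


#: parameter keys that carry no gradient (batch-norm running statistics)
BUFFER_KEYS = ("running_mean", "running_var")


def copy_params(params: list) -> list:
    return [{k: v.copy() for k, v in p.items()} for p in params]


def param_shapes(spec: NetworkSpec) -> list:
    """Expected parameter shapes per layer."""
    shapes = []
    for layer in spec.layers:
        if layer.transform_kind == "affine":
            n_in = math.prod(layer.in_shape)
            n_out = math.prod(layer.out_shape)
            s = {"W": (n_out, n_in), "b": (n_out,)}
        else:
            c_in, c_out, k = layer.in_shape[0], layer.out_shape[0], layer.kernel_size
            s = {"W": (c_out, c_in, k, k), "b": (c_out,)}
            if layer.has_batchnorm:
                s.update({"gamma": (c_out,), "beta": (c_out,),
                          "running_mean": (c_out,), "running_var": (c_out,)})
        shapes.append(s)
    return shapes


def check_params(spec: NetworkSpec, params: list) -> None:
    if len(params) != len(spec.layers):
        raise StructureError(
            f"expected {len(spec.layers)} parameter groups, got {len(params)}")
    for i, (p, ref) in enumerate(zip(params, param_shapes(spec))):
        for k, shape in ref.items():
            if k not in p:
                raise StructureError(f"layer {i}: missing parameter {k!r}")
            if p[k].shape != shape:
                raise StructureError(
                    f"layer {i}: parameter {k!r} has shape {p[k].shape}, "
                    f"expected {shape}")


def save_params(params: list, path) -> None:
    """Checkpoint parameters to an ``.npz`` archive (bit-exact round trip)."""
    arrays = {}
    for i, p in enumerate(params):
        for k, v in p.items():
            arrays[f"layer{i}:{k}"] = v
    np.savez(path, **arrays)


def load_params(path) -> list:
    with np.load(path) as data:
        layers: dict[int, dict] = {}
        for name in data.files:
            idx, key = name.split(":", 1)
            layers.setdefault(int(idx[5:]), {})[key] = data[name]
    return [layers[i] for i in sorted(layers)]
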