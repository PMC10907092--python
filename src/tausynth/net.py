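"""The 3D Dense-U-Net: encoder/decoder dense blocks joined by a bridge.

Topology: ``depth`` encoder levels, each a dense block followed by 2x
max-pooling; a bridge dense block at the bottom; ``depth`` decoder levels,
each an upsampling step (nearest-neighbour + convolution by default)
whose output is concatenated with the matching encoder skip before another
dense block; and a linear convolutional regression head mapping back to a
single channel of the same spatial size — SUVR in, SUVR out.

Dense wiring: within a block, layer ``j`` receives the concatenation of
the block input and the outputs of all previous layers, so its channel
count is ``c_in + j * f`` where ``f`` is the level's filter count. Filters
double at each encoder level (``base_filters * 2**level``) and halve back
up the decoder. The block's output is its last layer's activation, keeping
the filter-doubling arithmetic exact at every skip junction.

The full-size configuration is depth 4 on a 128^3 grid; the desk-scale
default used throughout the tests is depth 2 on 32^3.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import _nn
from ._nn import Tensor
from .volio import Volume

__all__ = [
    "NetworkSpec",
    "DenseUNet",
    "build_dense_unet",
    "parameter_count",
    "impute",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters; filter counts follow base_filters * 2**level."""

    depth: int = 4
    base_filters: int = 16
    layers_per_block: int = 2
    kernel_size: int = 3
    in_channels: int = 1
    activation: str = "relu"
    upsample_mode: str = "nearest+conv"
    final_activation: str = "linear"

    def __post_init__(self) -> None:
        if self.depth < 1 or self.base_filters < 1 or self.layers_per_block < 1:
            raise ValueError("depth, base_filters and layers_per_block must be >= 1")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd ('same' padding)")
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1 (2 for bimodal input)")
        if self.activation != "relu" or self.final_activation != "linear":
            raise ValueError("only relu activations with a linear head are supported")
        if self.upsample_mode not in ("nearest+conv",):
            raise ValueError(f"unsupported upsample_mode {self.upsample_mode!r}")

    def filters_at(self, level: int) -> int:
        return self.base_filters * 2**level


def _param_shapes(spec: NetworkSpec):
    """Yield (name, weight_shape) for every convolution, in forward order.

    Single source of truth for initialization, counting and checkpoints;
    biases are implied (one per output channel).
    """
    k = spec.kernel_size

    def block(prefix: str, c_in: int, f: int):
        for j in range(spec.layers_per_block):
            yield f"{prefix}.conv{j}", (f, c_in + j * f, k, k, k)

    c = spec.in_channels
    for lvl in range(spec.depth):
        f = spec.filters_at(lvl)
        yield from block(f"enc{lvl}", c, f)
        c = f
    f_bridge = spec.filters_at(spec.depth)
    yield from block("bridge", c, f_bridge)
    c = f_bridge
    for lvl in reversed(range(spec.depth)):
        f = spec.filters_at(lvl)
        yield f"up{lvl}.conv", (f, c, k, k, k)
        yield from block(f"dec{lvl}", 2 * f, f)  # upsampled f + skip f
        c = f
    yield "head.conv", (1, c, k, k, k)


def parameter_count(spec: NetworkSpec) -> int:
    """Trainable parameters as a pure function of the spec."""
    total = 0
    for _, shape in _param_shapes(spec):
        total += int(np.prod(shape)) + shape[0]  # weights + biases
    return total


class DenseUNet:
    """Model handle: parameter store plus forward/backward machinery."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        for name, shape in _param_shapes(spec):
            fan_in = int(np.prod(shape[1:]))
            limit = np.sqrt(6.0 / fan_in)  # He-uniform for ReLU layers
            self.params[f"{name}.w"] = rng.uniform(-limit, limit, size=shape).astype(np.float32)
            self.params[f"{name}.b"] = np.zeros(shape[0], dtype=np.float32)

    @property
    def parameter_count(self) -> int:
        return sum(int(v.size) for v in self.params.values())

    # -- forward ---------------------------------------------------------

    def _conv(self, name: str, x: Tensor) -> Tensor:
        w = Tensor(self.params[f"{name}.w"])
        h = _nn.conv3d(x, w, Tensor(self.params[f"{name}.b"]))
        self._param_nodes[f"{name}.w"] = w
        self._param_nodes[f"{name}.b"] = h.parents[2]
        return h

    def _dense_block(self, prefix: str, x: Tensor) -> Tensor:
        outs: list[Tensor] = []
        for j in range(self.spec.layers_per_block):
            inp = x if not outs else _nn.concat([x, *outs])
            outs.append(_nn.relu(self._conv(f"{prefix}.conv{j}", inp)))
        return outs[-1]

    def forward(self, x: np.ndarray) -> Tensor:
        """(in_channels, S, S, S) -> (1, S, S, S) tape output."""
        spec = self.spec
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[0] != spec.in_channels:
            raise ValueError(
                f"expected input of shape ({spec.in_channels}, S, S, S), got {x.shape}"
            )
        div = 2**spec.depth
        if any(s % div for s in x.shape[1:]):
            raise ValueError(
                f"spatial sides {x.shape[1:]} must be divisible by 2^depth = {div}"
            )
        self._param_nodes: dict[str, Tensor] = {}
        h = Tensor(x)
        skips: list[Tensor] = []
        for lvl in range(spec.depth):
            h = self._dense_block(f"enc{lvl}", h)
            skips.append(h)
            h = _nn.maxpool2(h)
        h = self._dense_block("bridge", h)
        for lvl in reversed(range(spec.depth)):
            h = _nn.relu(self._conv(f"up{lvl}.conv", _nn.upsample2(h)))
            h = _nn.concat([h, skips[lvl]])
            h = self._dense_block(f"dec{lvl}", h)
        return self._conv("head.conv", h)  # linear regression head

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Deterministic forward pass; returns the (1, S, S, S) array."""
        return self.forward(x).data.copy()

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Per-voxel MSE against target ``y`` (1, S, S, S) and parameter grads."""
        out = self.forward(x)
        loss = _nn.mse(out, np.asarray(y, dtype=np.float32))
        _nn.backward(loss)
        grads = {
            name: node.grad if node.grad is not None else np.zeros_like(self.params[name])
            for name, node in self._param_nodes.items()
        }
        return float(loss.data.item()), grads


def build_dense_unet(spec: NetworkSpec, seed: int = 0) -> DenseUNet:
    """Construct a seeded Dense-U-Net from an architecture spec."""
    return DenseUNet(spec, seed=seed)


def impute(model: DenseUNet, source: Volume | tuple[Volume, ...] | list[Volume]) -> Volume:
    """Synthesize a tau-like network-space volume from one or two source volumes.

    A tuple/list of volumes is stacked along the channel axis (bimodal
    input); the output always has a single channel and the input's spatial
    shape.
    """
    if isinstance(source, (tuple, list)):
        vols = list(source)
    else:
        vols = [source]
    if len(vols) != model.spec.in_channels:
        raise ValueError(
            f"model expects {model.spec.in_channels} input channel(s), got {len(vols)}"
        )
    shapes = {v.shape for v in vols}
    if len(shapes) != 1:
        raise ValueError(f"input volumes disagree on shape: {shapes}")
    x = np.stack([v.values for v in vols], axis=0)
    out = model.predict(x)[0].astype(np.float64)
    return Volume(values=out, voxel_size=vols[0].voxel_size, space="network")


def save_model(model: DenseUNet, path: str | Path) -> Path:
    """Write parameters (npz) plus a JSON sidecar embedding the NetworkSpec."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.params)
    path.with_suffix(".json").write_text(json.dumps(asdict(model.spec), indent=2))
    return path.with_suffix(".npz")


def load_model(path: str | Path) -> DenseUNet:
    path = Path(path)
    spec = NetworkSpec(**json.loads(path.with_suffix(".json").read_text()))
    model = DenseUNet(spec)
    with np.load(path.with_suffix(".npz")) as data:
        for k in model.params:
            model.params[k] = data[k].astype(np.float32)
    return model
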