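"""Declarative architecture specifications and the model builder.

Three reference CNNs for regulatory genomics are provided as layer lists:

* ``basset_spec`` — 600-nt multi-task chromatin-accessibility classifier
  (161 sigmoid outputs, three conv blocks, two 1000-unit dense blocks);
* ``deepstarr_spec`` — 249-nt two-task enhancer-activity regressor
  (four conv blocks, two 256-unit dense blocks, linear head);
* ``chipcnn_spec`` — 200-nt single-task TF-binding classifier.

Specs are backend-agnostic layer descriptions; :func:`build_model` performs
shape inference over the chain (pooled length = ``floor((len - size)/stride)
+ 1``, i.e. trailing remainders are dropped) and instantiates the numpy
backend.  Increasing ``input_length`` (e.g. by ``insert_max`` for
insertion-augmented training) only changes the first dense layer's fan-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from . import nn


@dataclass(frozen=True)
class LayerSpec:
    kind: str
    params: dict = field(default_factory=dict)

    _KINDS = {"conv1d", "batchnorm", "relu", "maxpool", "dropout", "dense", "flatten", "output"}

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")


@dataclass(frozen=True)
class ArchitectureSpec:
    name: str
    input_length: int
    layers: tuple[LayerSpec, ...]
    n_tasks: int
    head_activation: str  # "sigmoid" | "linear"
    input_channels: int = 4

    def to_yaml(self) -> str:
        payload = {
            "name": self.name,
            "input_length": self.input_length,
            "input_channels": self.input_channels,
            "n_tasks": self.n_tasks,
            "head_activation": self.head_activation,
            "layers": [{"kind": l.kind, "params": dict(l.params)} for l in self.layers],
        }
        return yaml.safe_dump(payload, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ArchitectureSpec":
        d = yaml.safe_load(text)
        return cls(
            name=d["name"],
            input_length=int(d["input_length"]),
            input_channels=int(d.get("input_channels", 4)),
            n_tasks=int(d["n_tasks"]),
            head_activation=d["head_activation"],
            layers=tuple(LayerSpec(l["kind"], dict(l.get("params", {}))) for l in d["layers"]),
        )


def _conv_block(filters: int, width: int, pool: int, dropout: float | None = None):
    block = [
        LayerSpec("conv1d", {"filters": filters, "width": width, "stride": 1}),
        LayerSpec("batchnorm"),
        LayerSpec("relu"),
    ]
    if dropout is not None:
        block.append(LayerSpec("dropout", {"rate": dropout}))
    block.append(LayerSpec("maxpool", {"size": pool, "stride": pool}))
    return block


def _dense_block(units: int, dropout: float):
    return [
        LayerSpec("dense", {"units": units}),
        LayerSpec("batchnorm"),
        LayerSpec("relu"),
        LayerSpec("dropout", {"rate": dropout}),
    ]


def basset_spec(input_length: int = 600, n_tasks: int = 161) -> ArchitectureSpec:
    """Basset-style multi-task chromatin-accessibility classifier."""
    layers = (
        *_conv_block(300, 19, 3),
        *_conv_block(200, 11, 4),
        *_conv_block(200, 7, 2),
        LayerSpec("flatten"),
        *_dense_block(1000, 0.3),
        *_dense_block(1000, 0.3),
        LayerSpec("output", {"units": n_tasks}),
    )
    return ArchitectureSpec("basset", input_length, layers, n_tasks, "sigmoid")


def deepstarr_spec(input_length: int = 249, n_tasks: int = 2) -> ArchitectureSpec:
    """DeepSTARR-style two-task enhancer-activity regressor."""
    layers = (
        *_conv_block(256, 7, 2),
        *_conv_block(60, 3, 2),
        *_conv_block(60, 5, 2),
        *_conv_block(120, 3, 2),
        LayerSpec("flatten"),
        *_dense_block(256, 0.4),
        *_dense_block(256, 0.4),
        LayerSpec("output", {"units": n_tasks}),
    )
    return ArchitectureSpec("deepstarr", input_length, layers, n_tasks, "linear")


def chipcnn_spec(input_length: int = 200, n_tasks: int = 1) -> ArchitectureSpec:
    """Compact CNN for single-task TF-binding classification."""
    layers = (
        *_conv_block(64, 7, 4, dropout=0.2),
        *_conv_block(96, 5, 4, dropout=0.2),
        *_conv_block(128, 5, 2, dropout=0.2),
        LayerSpec("flatten"),
        *_dense_block(256, 0.5),
        LayerSpec("output", {"units": n_tasks}),
    )
    return ArchitectureSpec("chipcnn", input_length, layers, n_tasks, "sigmoid")


def mini_cnn_spec(
    input_length: int = 200,
    n_tasks: int = 1,
    filters: tuple[int, ...] = (48,),
    widths: tuple[int, ...] = (9,),
    pools: tuple = ("global",),
    dense_units: int = 32,
    head_activation: str = "sigmoid",
) -> ArchitectureSpec:
    """Miniature CNN for desk-scale experiments and the test suite.

    The default is a single conv block whose max pool spans the whole
    feature map ("global"): position-invariant motif detection generalises
    from a couple of thousand sequences, where positional dense layers
    would simply memorise.
    """
    conv_layers: list[LayerSpec] = []
    length = input_length
    for f, w, p in zip(filters, widths, pools):
        length = length - w + 1
        if p == "global":
            p = length
        conv_layers.extend(_conv_block(f, w, p))
        length //= p
    layers = (
        *conv_layers,
        LayerSpec("flatten"),
        *_dense_block(dense_units, 0.2),
        LayerSpec("output", {"units": n_tasks}),
    )
    return ArchitectureSpec("mini_cnn", input_length, layers, n_tasks, head_activation)


PRESETS = {
    "basset": basset_spec,
    "deepstarr": deepstarr_spec,
    "chipcnn": chipcnn_spec,
    "mini": mini_cnn_spec,
}


def build_model(spec: ArchitectureSpec, seed: int = 0) -> nn.Network:
    """Instantiate a spec as a trainable network, validating the layer chain.

    Shape inference runs at build time; a chain whose pooled length reaches
    zero raises a ``ValueError`` naming the offending layer.
    """
    rng = np.random.default_rng(seed)
    length = spec.input_length
    channels = spec.input_channels
    flat: int | None = None
    layers: list[nn.layers.Layer] = []
    for i, ls in enumerate(spec.layers):
        where = f"layer {i} ({ls.kind})"
        if ls.kind == "conv1d":
            if flat is not None:
                raise ValueError(f"{where}: convolution after flatten is not supported")
            layer = nn.Conv1D(channels, ls.params["filters"], ls.params["width"], rng)
            try:
                length = layer.output_length(length)
            except ValueError as exc:
                raise ValueError(f"{where}: {exc}") from None
            channels = ls.params["filters"]
        elif ls.kind == "maxpool":
            layer = nn.MaxPool1D(ls.params["size"])
            try:
                length = layer.output_length(length)
            except ValueError as exc:
                raise ValueError(f"{where}: {exc}") from None
        elif ls.kind == "batchnorm":
            layer = nn.BatchNorm(channels if flat is None else flat)
        elif ls.kind == "relu":
            layer = nn.ReLU()
        elif ls.kind == "dropout":
            layer = nn.Dropout(ls.params["rate"], rng)
        elif ls.kind == "flatten":
            layer = nn.Flatten()
            flat = length * channels
        elif ls.kind == "dense":
            if flat is None:
                raise ValueError(f"{where}: dense layer requires a preceding flatten")
            layer = nn.Dense(flat, ls.params["units"], rng)
            flat = ls.params["units"]
        elif ls.kind == "output":
            if flat is None:
                raise ValueError(f"{where}: output layer requires a preceding flatten")
            layer = nn.Dense(flat, ls.params["units"], rng)
            flat = ls.params["units"]
            layers.append(layer)
            if spec.head_activation == "sigmoid":
                layers.append(nn.Sigmoid())
            elif spec.head_activation != "linear":
                raise ValueError(f"unknown head activation {spec.head_activation!r}")
            continue
        else:  # pragma: no cover
            raise ValueError(f"{where}: unknown kind")
        layers.append(layer)
    if flat != spec.n_tasks:
        raise ValueError(
            f"output layer produces {flat} units but spec declares n_tasks={spec.n_tasks}"
        )
    return nn.Network(layers)


def save_checkpoint(path, model: nn.Network, spec: ArchitectureSpec) -> None:
    """Save weights plus the embedded spec so a model can be rebuilt blind."""
    arrays = {}
    for i, layer_state in enumerate(model.get_state()):
        for j, arr in enumerate(layer_state):
            arrays[f"l{i}_{j}"] = arr
    np.savez(path, __spec__=np.array(spec.to_yaml()), **arrays)


def load_checkpoint(path) -> tuple[nn.Network, ArchitectureSpec]:
    data = np.load(path, allow_pickle=False)
    spec = ArchitectureSpec.from_yaml(str(data["__spec__"]))
    model = build_model(spec)
    state: list[list[np.ndarray]] = []
    for i in range(len(model.layers)):
        layer_state = []
        j = 0
        while f"l{i}_{j}" in data:
            layer_state.append(data[f"l{i}_{j}"])
            j += 1
        state.append(layer_state)
    model.set_state(state)
    return model, spec
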