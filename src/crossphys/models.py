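"""Declarative CNN architectures with closed-form shape inference.

The two study networks are described as ordered :class:`LayerSpec` lists from
which everything else is derived: the runtime network, the per-layer output
shapes (valid/unpadded arithmetic, ``out = floor((in − k)/stride) + 1``),
parameter counts under any freeze set, and a JSON serialization.

* Seizure prediction: input 5120 samples (10 s of GFP at 512 Hz), four
  conv + batch-norm + max-pool stages, global average pooling, dense
  256 → 128 → 2.
* Sleep staging: input 3000 samples (30 s at 100 Hz), three named blocks
  (block_1/block_2: two conv + BN pairs and an average pool; block_3: one
  conv + BN and the global average pool), dense 32 → 5.

Two shape entries printed for these architectures are internally
inconsistent and are corrected here: the second seizure conv outputs 64
channels (its filter count), and the second sleep conv outputs length 2992
(= 2996 − 5 + 1), which the downstream pooled length 1496 confirms.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import network as net

LAYER_KINDS = ("conv1d", "batch_norm", "max_pool1d", "avg_pool1d", "global_avg_pool", "dense")


@dataclass(frozen=True)
class LayerSpec:
    name: str
    kind: str
    filter_size: int | None = None
    n_filters: int | None = None
    stride: int | None = None
    units: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"{self.name}: unknown layer kind {self.kind!r}")
        if self.kind == "conv1d" and not (self.filter_size and self.n_filters and self.stride):
            raise ValueError(f"{self.name}: conv1d needs filter_size, n_filters, stride")
        if self.kind in ("max_pool1d", "avg_pool1d") and not (self.filter_size and self.stride):
            raise ValueError(f"{self.name}: pooling needs filter_size and stride")
        if self.kind == "dense" and not self.units:
            raise ValueError(f"{self.name}: dense needs units")
        if self.stride is not None and self.stride < 1:
            raise ValueError(f"{self.name}: stride must be >= 1")


@dataclass(frozen=True)
class ModelSpec:
    layers: tuple[LayerSpec, ...]
    input_len: int
    input_channels: int
    n_classes: int
    block_boundaries: dict[str, tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        last = self.layers[-1]
        if last.kind != "dense" or last.units != self.n_classes:
            raise ValueError("spec must end with a dense layer of n_classes units")
        if self.block_boundaries:
            named = [n for layers in self.block_boundaries.values() for n in layers]
            feature = [l.name for l in self.layers if l.kind != "dense"]
            if sorted(named) != sorted(feature):
                raise ValueError(
                    f"blocks must partition the pre-dense feature layers; "
                    f"blocks cover {sorted(named)}, features are {sorted(feature)}"
                )

    def layer(self, name: str) -> LayerSpec:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(f"no layer named {name!r}")

    def feature_layer_names(self) -> tuple[str, ...]:
        """Ordered conv/BN/pool layers before the global pooling stage."""
        out = []
        for l in self.layers:
            if l.kind in ("global_avg_pool", "dense"):
                break
            out.append(l.name)
        return tuple(out)


@dataclass(frozen=True)
class TrainHyper:
    """Training hyperparameters; the two experiments' published settings are
    available as :func:`seizure_hyper` and :func:`sleep_hyper`."""

    batch_size: int = 128
    lr: float = 2e-4
    min_lr: float = 1e-5
    max_epochs: int = 100
    early_stop_patience: int | None = None
    reduce_lr_factor: float = 0.5
    reduce_lr_patience: int = 5
    stop_at_val_accuracy: float | None = None
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if not self.min_lr < self.lr:
            raise ValueError(f"min_lr ({self.min_lr}) must be < lr ({self.lr})")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


def seizure_hyper(**overrides) -> TrainHyper:
    """Adam, batch 128, lr 2e-4 reduced on plateau down to 1e-5."""
    base = dict(batch_size=128, lr=2e-4, min_lr=1e-5)
    base.update(overrides)
    return TrainHyper(**base)


def sleep_hyper(**overrides) -> TrainHyper:
    """Adam, batch 128, lr 1e-3 down to 1e-4, early stopping patience 10."""
    base = dict(batch_size=128, lr=1e-3, min_lr=1e-4, early_stop_patience=10)
    base.update(overrides)
    return TrainHyper(**base)


def seizure_model_spec() -> ModelSpec:
    """The seizure-prediction CNN: 4×(conv, BN, max-pool) + GAP + 3 dense."""
    layers = []
    conv_cfg = [(32, 2), (64, 2), (64, 2), (128, 1)]
    for i, (filters, stride) in enumerate(conv_cfg, start=1):
        layers += [
            LayerSpec(f"conv1d_{i}", "conv1d", filter_size=10, n_filters=filters, stride=stride),
            LayerSpec(f"batch_normalization_{i}", "batch_norm"),
            LayerSpec(f"max_pooling1d_{i}", "max_pool1d", filter_size=3, stride=1),
        ]
    layers += [
        LayerSpec("global_average_pooling1d", "global_avg_pool"),
        LayerSpec("dense_1", "dense", units=256),
        LayerSpec("dense_2", "dense", units=128),
        LayerSpec("dense_3", "dense", units=2),
    ]
    return ModelSpec(layers=tuple(layers), input_len=5120, input_channels=1, n_classes=2)


def sleep_model_spec() -> ModelSpec:
    """The sleep-staging CNN: three named blocks + dense 32 → 5."""
    layers = (
        LayerSpec("conv1d_1", "conv1d", filter_size=5, n_filters=16, stride=1),
        LayerSpec("batch_normalization_1", "batch_norm"),
        LayerSpec("conv1d_2", "conv1d", filter_size=5, n_filters=16, stride=1),
        LayerSpec("batch_normalization_2", "batch_norm"),
        LayerSpec("average_pooling1d_1", "avg_pool1d", filter_size=2, stride=2),
        LayerSpec("conv1d_3", "conv1d", filter_size=5, n_filters=32, stride=1),
        LayerSpec("batch_normalization_3", "batch_norm"),
        LayerSpec("conv1d_4", "conv1d", filter_size=5, n_filters=32, stride=1),
        LayerSpec("batch_normalization_4", "batch_norm"),
        LayerSpec("average_pooling1d_2", "avg_pool1d", filter_size=2, stride=2),
        LayerSpec("conv1d_5", "conv1d", filter_size=5, n_filters=32, stride=1),
        LayerSpec("batch_normalization_5", "batch_norm"),
        LayerSpec("global_average_pooling1d", "global_avg_pool"),
        LayerSpec("dense_1", "dense", units=32),
        LayerSpec("dense_2", "dense", units=5),
    )
    blocks = {
        "block_1": tuple(l.name for l in layers[0:5]),
        "block_2": tuple(l.name for l in layers[5:10]),
        "block_3": tuple(l.name for l in layers[10:13]),
    }
    return ModelSpec(layers=layers, input_len=3000, input_channels=1, n_classes=5, block_boundaries=blocks)


@dataclass(frozen=True)
class LayerShape:
    """Output shape of one layer: (length, channels); length is None once the
    feature map has collapsed to a vector (global pooling, dense)."""

    name: str
    length: int | None
    channels: int


def infer_shapes(spec: ModelSpec) -> list[LayerShape]:
    """Closed-form per-layer output shapes under valid (unpadded) arithmetic."""
    length: int | None = spec.input_len
    channels = spec.input_channels
    shapes: list[LayerShape] = []
    for l in spec.layers:
        if l.kind == "conv1d":
            length = (length - l.filter_size) // l.stride + 1
            channels = l.n_filters
        elif l.kind in ("max_pool1d", "avg_pool1d"):
            length = (length - l.filter_size) // l.stride + 1
        elif l.kind == "batch_norm":
            pass
        elif l.kind == "global_avg_pool":
            length = None
        elif l.kind == "dense":
            if length is not None:
                raise ValueError(
                    f"{l.name}: dense layers must follow global pooling in this architecture family"
                )
            channels = l.units
        if length is not None and length < 1:
            raise ValueError(f"{l.name}: output length {length} < 1 — input too short for this stack")
        shapes.append(LayerShape(name=l.name, length=length, channels=channels))
    return shapes


def shape_table(spec: ModelSpec) -> str:
    """Human-readable shape table (``name  kind  output``)."""
    rows = []
    for l, s in zip(spec.layers, infer_shapes(spec)):
        out = f"{s.length} x {s.channels}" if s.length is not None else str(s.channels)
        rows.append(f"{l.name:28s} {l.kind:16s} {out}")
    return "\n".join(rows)


def build_model(spec: ModelSpec, seed: int = 0) -> net.Network:
    """Instantiate a trainable network from a spec with seeded initialization.

    Hidden activations are rectified-linear, fused after a conv's batch norm
    (or after the conv itself when no BN follows); the final dense layer is
    linear, with softmax applied by the loss/prediction paths.
    """
    shapes = infer_shapes(spec)
    layers: list[net.Layer] = []
    in_ch = spec.input_channels
    n = len(spec.layers)
    for i, l in enumerate(spec.layers):
        followed_by_bn = i + 1 < n and spec.layers[i + 1].kind == "batch_norm"
        if l.kind == "conv1d":
            layers.append(net.Conv1D(l.name, in_ch, l.n_filters, l.filter_size, l.stride, relu=not followed_by_bn))
        elif l.kind == "batch_norm":
            layers.append(net.BatchNorm1D(l.name, in_ch, relu=True))
        elif l.kind == "max_pool1d":
            layers.append(net.MaxPool1D(l.name, l.filter_size, l.stride))
        elif l.kind == "avg_pool1d":
            layers.append(net.AvgPool1D(l.name, l.filter_size, l.stride))
        elif l.kind == "global_avg_pool":
            layers.append(net.GlobalAvgPool(l.name))
        elif l.kind == "dense":
            is_last = i == n - 1
            layers.append(net.Dense(l.name, in_ch, l.units, relu=not is_last))
        in_ch = shapes[i].channels
    return net.Network(layers, seed=seed)


def count_parameters(spec: ModelSpec, frozen_set: set[str] | frozenset[str] = frozenset()) -> tuple[int, int]:
    """Exact (total, trainable) learnable-parameter counts under a freeze set.

    Frozen layers' weights — including batch-norm affine terms — are excluded
    from the trainable count. Unknown names in ``frozen_set`` raise.
    """
    known = {l.name for l in spec.layers}
    unknown = sorted(set(frozen_set) - known)
    if unknown:
        raise KeyError(f"unknown layer name(s) in frozen_set: {unknown}")
    total = trainable = 0
    in_ch = spec.input_channels
    for l, s in zip(spec.layers, infer_shapes(spec)):
        if l.kind == "conv1d":
            n = l.n_filters * in_ch * l.filter_size + l.n_filters
        elif l.kind == "batch_norm":
            n = 2 * in_ch
        elif l.kind == "dense":
            n = in_ch * l.units + l.units
        else:
            n = 0
        total += n
        if l.name not in frozen_set:
            trainable += n
        in_ch = s.channels
    return total, trainable


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def spec_to_dict(spec: ModelSpec) -> dict:
    d = asdict(spec)
    d["layers"] = [
        {k: v for k, v in asdict(l).items() if v is not None} for l in spec.layers
    ]
    return d


def spec_from_dict(d: dict) -> ModelSpec:
    layers = tuple(LayerSpec(**l) for l in d["layers"])
    blocks = d.get("block_boundaries")
    if blocks:
        blocks = {k: tuple(v) for k, v in blocks.items()}
    return ModelSpec(
        layers=layers,
        input_len=d["input_len"],
        input_channels=d["input_channels"],
        n_classes=d["n_classes"],
        block_boundaries=blocks,
    )


def save_spec(spec: ModelSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(spec_to_dict(spec), indent=2) + "\n")


def load_spec(path: str | Path) -> ModelSpec:
    return spec_from_dict(json.loads(Path(path).read_text()))
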