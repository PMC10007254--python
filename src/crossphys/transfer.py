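"""Layer/block-freezing transfer: the study's fine-tuning protocol.

Experiment 1 freezes the first *n* of the seizure model's 12 ordered feature
layers (four conv–BN–maxpool stages of 3 layers each), with n ∈ {3, 6, 9, 12}
landing on stage boundaries, then retrains the unfrozen remainder on one
patient's windows. Experiment 2 freezes a contiguous prefix of the sleep
model's named blocks (block_1, block_1–2 or block_1–3) before fine-tuning the
EEG-pretrained network on ECG epochs.

"Frozen" means: excluded from gradient updates (parameters bit-identical
after any amount of fine-tuning) and, for batch-norm layers, running in
inference mode on the stored source statistics (optionally re-estimated on
the target domain). ECG at 256 Hz is polyphase-resampled to the model's
100-Hz input grid first, since transfer requires an identical input shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .models import ModelSpec, TrainHyper
from .network import Network
from .signal_io import EpochSet, Recording
from .training import fit

ALLOWED_FREEZE_DEPTHS = (3, 6, 9, 12)
BLOCK_ORDER = ("block_1", "block_2", "block_3")


@dataclass(frozen=True)
class FreezeSpec:
    """Which pretrained layers stay fixed during fine-tuning.

    ``first_n_layers`` counts over the ordered pre-global feature layers;
    ``named_blocks`` freezes whole blocks, contiguous from block_1. In strict
    mode the depth must be one of the studied values {3, 6, 9, 12}.
    """

    mode: str  # "first_n_layers" | "named_blocks"
    n: int | None = None
    blocks: tuple[str, ...] = ()
    strict: bool = True
    bn_mode: str = "source"  # frozen batch-norm statistics: source | reestimate

    def __post_init__(self) -> None:
        if self.mode == "first_n_layers":
            if self.n is None:
                raise ValueError("first_n_layers mode needs n")
            if self.strict and self.n not in ALLOWED_FREEZE_DEPTHS:
                raise ValueError(
                    f"freeze depth n={self.n} is not one of the studied depths {ALLOWED_FREEZE_DEPTHS} "
                    "(pass strict=False to allow)"
                )
            if self.n < 0:
                raise ValueError("n must be >= 0")
        elif self.mode == "named_blocks":
            blocks = tuple(self.blocks)
            expected = BLOCK_ORDER[: len(blocks)]
            if blocks != expected:
                raise ValueError(
                    f"blocks must be contiguous from block_1 (got {blocks}, expected a prefix of {BLOCK_ORDER})"
                )
            object.__setattr__(self, "blocks", blocks)
        else:
            raise ValueError(f"unknown freeze mode {self.mode!r}")

    def layer_names(self, spec: ModelSpec) -> tuple[str, ...]:
        """Resolve the freeze set to concrete layer names for a model spec."""
        if self.mode == "first_n_layers":
            feature = spec.feature_layer_names()
            if self.n > len(feature):
                raise ValueError(f"n={self.n} exceeds the {len(feature)} feature layers")
            return feature[: self.n]
        if spec.block_boundaries is None:
            raise ValueError("named_blocks freezing needs a spec with block_boundaries")
        missing = [b for b in self.blocks if b not in spec.block_boundaries]
        if missing:
            raise KeyError(f"spec has no block(s) {missing}")
        names: list[str] = []
        for b in self.blocks:
            names.extend(spec.block_boundaries[b])
        return tuple(names)


def freeze(network: Network, freeze_spec: FreezeSpec, model_spec: ModelSpec) -> Network:
    """Apply a freeze mask in place; returns the network for chaining."""
    names = set(freeze_spec.layer_names(model_spec))
    network.set_frozen(names, bn_mode=freeze_spec.bn_mode)
    return network


def fine_tune(
    network: Network,
    model_spec: ModelSpec,
    target_epochs: EpochSet,
    freeze_spec: FreezeSpec,
    hyper: TrainHyper,
    seed: int = 0,
    label_order: tuple[str, ...] | None = None,
    val_fraction: float = 0.15,
) -> dict:
    """Freeze, then retrain the unfrozen layers on the target epochs.

    Frozen parameters are bit-identical to the pretrained values afterwards
    (asserted). Returns the training history.
    """
    from .training import _stratified_split, encode_labels  # local import avoids cycle at module load

    expected = getattr(model_spec, "input_len")
    if target_epochs.windows.shape[1] != expected:
        raise ValueError(
            f"target windows have {target_epochs.windows.shape[1]} samples; "
            f"the network expects input length {expected}"
        )
    freeze(network, freeze_spec, model_spec)
    before = {k: v.copy() for k, v in network.get_state().items()}

    if label_order is None:
        label_order = tuple(sorted(np.unique(target_epochs.labels).tolist()))
    y = encode_labels(target_epochs.labels, label_order)
    X = target_epochs.windows[:, None, :]
    rng = np.random.default_rng(seed)
    tr, va = _stratified_split(target_epochs.labels, np.arange(len(target_epochs)), 1 - val_fraction, rng)
    history = fit(network, X[tr], y[tr], X[va], y[va], hyper, seed=seed)

    frozen_param_keys = {
        f"{name}/{p}" for name in network.frozen_layers for p in ("W", "b", "gamma", "beta")
    }
    after = network.get_state()
    for key in after:
        if key in frozen_param_keys and not np.array_equal(before[key], after[key]):
            raise AssertionError(f"frozen parameter {key} changed during fine-tuning")
    return history


def adapt_input(recording: Recording, target_fs: float, strict: bool = True) -> Recording:
    """Polyphase-resample a recording to the model's input rate.

    Downsampling only in strict mode (the 256-Hz ECG is brought down to the
    100-Hz grid of the sleep model); identical rates return the recording
    unchanged. Annotations and provenance are preserved.
    """
    if recording.fs_hz == target_fs:
        return recording
    if strict and target_fs > recording.fs_hz:
        raise ValueError(
            f"upsampling {recording.fs_hz} -> {target_fs} Hz requested in strict mode"
        )
    frac = Fraction(target_fs / recording.fs_hz).limit_denominator(10000)
    out = sps.resample_poly(recording.signal.astype(np.float64), frac.numerator, frac.denominator, axis=1)
    from dataclasses import replace

    return replace(recording, signal=out, fs_hz=target_fs)
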