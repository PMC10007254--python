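"""Shared fixtures: session-scoped synthetic epoch sets and tiny model specs.

The session fixtures are the study-condition datasets (200 windows per state
after balancing); generating the 29-channel seizure recording dominates their
cost, so every test that needs conditioned windows shares these objects.
"""

from __future__ import annotations

import numpy as np
import pytest

from crossphys.models import LayerSpec, ModelSpec
from crossphys.pipeline import seizure_epochset, sleep_epochset
from crossphys.signal_io import EpochSet


@pytest.fixture(scope="session")
def seizure_epochs() -> EpochSet:
    """Balanced four-state seizure windows from one synthetic subject."""
    return seizure_epochset(seed=1, windows_per_state=200)


@pytest.fixture(scope="session")
def sleep_eeg_epochs() -> EpochSet:
    """Balanced five-stage sleep EEG windows from one synthetic night."""
    return sleep_epochset("eeg", seed=1, windows_per_state=200)


@pytest.fixture(scope="session")
def sleep_ecg_epochs() -> EpochSet:
    """Balanced five-stage sleep ECG windows (resampled to the 100-Hz grid)."""
    return sleep_epochset("ecg", seed=2001, windows_per_state=200)


def tiny_model_spec(input_len: int = 64, n_classes: int = 2) -> ModelSpec:
    """A miniature conv net for fast training-loop tests."""
    return ModelSpec(
        layers=(
            LayerSpec("conv1d_1", "conv1d", filter_size=5, n_filters=8, stride=2),
            LayerSpec("batch_normalization_1", "batch_norm"),
            LayerSpec("max_pooling1d_1", "max_pool1d", filter_size=2, stride=2),
            LayerSpec("global_average_pooling1d", "global_avg_pool"),
            LayerSpec("dense_1", "dense", units=16),
            LayerSpec("dense_2", "dense", units=n_classes),
        ),
        input_len=input_len,
        input_channels=1,
        n_classes=n_classes,
    )


def tiny_two_class_epochs(n_per_class: int = 60, n_samples: int = 64, fs: float = 64.0, seed: int = 0) -> EpochSet:
    """Separable toy windows: an 8-Hz tone in noise vs pure noise."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / fs
    tone = np.sin(2 * np.pi * 8.0 * t)
    windows, labels = [], []
    for _ in range(n_per_class):
        windows.append(2.0 * tone + 0.5 * rng.standard_normal(n_samples))
        labels.append("tone")
        windows.append(0.5 * rng.standard_normal(n_samples))
        labels.append("noise")
    n = len(labels)
    return EpochSet(
        windows=np.array(windows, dtype=np.float32),
        labels=np.array(labels),
        groups=np.full(n, "toy"),
        dataset_tags=np.full(n, "toy"),
        fs_hz=fs,
        window_s=n_samples / fs,
    )
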