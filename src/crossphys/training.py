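"""Split regimes, cross-validation folds, and the training loop.

Three split regimes mirror the study designs:

* **recordwise** — windows pooled over all subjects, split at random with
  stratification by state (90:10 in the seizure experiment, 80:20 in the
  sleep experiment). Subject identity leaks across the split; this is the
  optimistic baseline.
* **subjectwise** — membership decided solely by source dataset tag (one
  corpus trains, the other tests), so no subject appears on both sides.
* **patient_specific** — a recordwise split *within* one subject's windows,
  used as the fine-tuning set for transfer.

Training uses Adam (batch 128), reduce-on-plateau learning-rate decay down to
``min_lr`` and optional early stopping on validation loss (patience 10 in the
sleep experiment); the best-validation-loss weights are restored at the end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .models import TrainHyper
from .network import Adam, Network, softmax_cross_entropy
from .signal_io import EpochSet


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite; carries the epoch index."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite training loss at epoch {epoch}")
        self.epoch = epoch


@dataclass
class SplitPlan:
    """Train/test index sets over an :class:`EpochSet`, plus optional folds."""

    regime: str
    train_idx: np.ndarray
    test_idx: np.ndarray
    folds: list[np.ndarray] = field(default_factory=list)
    seed: int = 0
    repeat_index: int = 0

    def __post_init__(self) -> None:
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError("train and test index sets overlap")
        if self.folds:
            self.check_folds()

    def check_folds(self) -> None:
        allf = np.concatenate(self.folds) if self.folds else np.empty(0, dtype=int)
        if len(np.unique(allf)) != len(allf):
            raise ValueError("folds contain duplicate indices")
        if not np.array_equal(np.sort(allf), np.sort(self.train_idx)):
            raise ValueError("folds must partition the training set")
        if np.intersect1d(allf, self.test_idx).size:
            raise ValueError("a test index appears in a training fold")


def _stratified_split(labels: np.ndarray, idx: np.ndarray, ratio: float, rng: np.random.Generator):
    train_parts, test_parts = [], []
    for state in np.unique(labels[idx]):
        state_idx = idx[labels[idx] == state]
        if len(state_idx) < 2:
            raise ValueError(f"state {state!r} has fewer than 2 windows; cannot split")
        perm = rng.permutation(state_idx)
        n_train = math.floor(ratio * len(perm))
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))


def split_recordwise(epochs: EpochSet, ratio: float = 0.9, seed: int = 0) -> SplitPlan:
    """Random stratified split: per state, ``floor(ratio·n)`` windows train.

    With 198 windows per state at 90:10 this gives the study's 178 train /
    20 test per state.
    """
    if not (0 < ratio < 1):
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    rng = np.random.default_rng(seed)
    train, test = _stratified_split(epochs.labels, np.arange(len(epochs)), ratio, rng)
    return SplitPlan(regime="recordwise", train_idx=train, test_idx=test, seed=seed)


def split_subjectwise(epochs: EpochSet, train_dataset_tag: str, test_dataset_tag: str) -> SplitPlan:
    """Cross-dataset split: membership decided solely by dataset tag."""
    tags = epochs.dataset_tags
    for tag in (train_dataset_tag, test_dataset_tag):
        if not (tags == tag).any():
            raise ValueError(f"dataset tag {tag!r} not present in the epoch set")
    train = np.nonzero(tags == train_dataset_tag)[0]
    test = np.nonzero(tags == test_dataset_tag)[0]
    shared = np.intersect1d(np.unique(epochs.groups[train]), np.unique(epochs.groups[test]))
    if shared.size:
        raise ValueError(
            f"subject(s) {shared.tolist()} appear in both datasets — subjectwise integrity violated"
        )
    return SplitPlan(regime="subjectwise", train_idx=train, test_idx=test)


def split_patient_specific(epochs: EpochSet, subject_id: str, ratio: float = 0.9, seed: int = 0) -> SplitPlan:
    """Per-subject stratified split over that subject's windows only."""
    idx = np.nonzero(epochs.groups == subject_id)[0]
    if idx.size == 0:
        raise ValueError(f"subject {subject_id!r} has no windows")
    rng = np.random.default_rng(seed)
    train, test = _stratified_split(epochs.labels, idx, ratio, rng)
    return SplitPlan(regime="patient_specific", train_idx=train, test_idx=test, seed=seed)


def make_folds(plan: SplitPlan, epochs: EpochSet, k: int, seed: int | None = None) -> SplitPlan:
    """Attach k near-equal state-stratified folds partitioning the train set."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(plan.train_idx) < k:
        raise ValueError(f"training set of {len(plan.train_idx)} cannot form {k} folds")
    rng = np.random.default_rng(plan.seed if seed is None else seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    labels = epochs.labels
    offset = 0
    for state in np.unique(labels[plan.train_idx]):
        state_idx = plan.train_idx[labels[plan.train_idx] == state]
        perm = rng.permutation(state_idx)
        # round-robin with a rotating offset so fold sizes stay near-equal
        for j, ix in enumerate(perm):
            folds[(j + offset) % k].append(int(ix))
        offset = (offset + len(perm)) % k
    plan.folds = [np.sort(np.array(f, dtype=int)) for f in folds]
    plan.check_folds()
    return plan


def encode_labels(labels: np.ndarray, label_order: tuple[str, ...]) -> np.ndarray:
    lut = {s: i for i, s in enumerate(label_order)}
    unknown = sorted(set(labels.tolist()) - set(label_order))
    if unknown:
        raise ValueError(f"label(s) {unknown} not in label order {label_order}")
    return np.array([lut[s] for s in labels], dtype=int)


def _eval_on(network: Network, X: np.ndarray, y: np.ndarray, batch_size: int) -> tuple[float, float]:
    """(mean loss, accuracy) on a dataset in inference mode."""
    losses, correct = [], 0
    for i in range(0, len(X), batch_size):
        logits = network.forward(X[i : i + batch_size], training=False)
        loss, _ = softmax_cross_entropy(logits, y[i : i + batch_size])
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) == y[i : i + batch_size]).sum())
    return float(np.sum(losses) / len(X)), correct / len(X)


def fit(
    network: Network,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    hyper: TrainHyper,
    seed: int = 0,
) -> dict:
    """Train a network; returns the per-epoch history.

    Implements reduce-on-plateau (factor/patience from ``hyper``, floored at
    ``min_lr``), optional early stopping on validation loss, an optional
    validation-accuracy convergence stop for benchmark runs, and restoration
    of the best-validation-loss weights.
    """
    rng = np.random.default_rng(seed)
    opt = Adam(lr=hyper.lr)
    history: dict[str, list] = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [], "lr": []}
    best_val = np.inf
    best_state = network.get_state()
    plateau = early = 0

    X_train = np.ascontiguousarray(X_train, dtype=np.float32)
    X_val = np.ascontiguousarray(X_val, dtype=np.float32)
    for epoch in range(hyper.max_epochs):
        order = rng.permutation(len(X_train))
        losses, correct = [], 0
        for i in range(0, len(order), hyper.batch_size):
            batch = order[i : i + hyper.batch_size]
            logits = network.forward(X_train[batch], training=True)
            loss, dlogits = softmax_cross_entropy(logits, y_train[batch])
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            network.backward(dlogits)
            opt.step(network)
            losses.append(loss * len(batch))
            correct += int((logits.argmax(axis=1) == y_train[batch]).sum())
        val_loss, val_acc = _eval_on(network, X_val, y_val, hyper.batch_size)
        history["train_loss"].append(float(np.sum(losses) / len(order)))
        history["train_acc"].append(correct / len(order))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        history["lr"].append(opt.lr)

        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = network.get_state()
            plateau = early = 0
        else:
            plateau += 1
            early += 1
            if plateau >= hyper.reduce_lr_patience:
                opt.lr = max(opt.lr * hyper.reduce_lr_factor, hyper.min_lr)
                plateau = 0
        if hyper.stop_at_val_accuracy is not None and val_acc >= hyper.stop_at_val_accuracy:
            best_state = network.get_state()
            break
        if hyper.early_stop_patience is not None and early >= hyper.early_stop_patience:
            break
    network.set_state(best_state)
    return history


def train_model(
    network: Network,
    epochs: EpochSet,
    plan: SplitPlan,
    hyper: TrainHyper,
    seed: int = 0,
    label_order: tuple[str, ...] | None = None,
    val_fold: int = 0,
    val_fraction: float = 0.1,
) -> dict:
    """Train on a split plan's training set; validation comes from the held-out
    fold ``val_fold`` when folds exist, else a stratified ``val_fraction``."""
    if label_order is None:
        label_order = tuple(sorted(np.unique(epochs.labels).tolist()))
    y = encode_labels(epochs.labels, label_order)
    X = epochs.windows[:, None, :]
    if plan.folds:
        val_idx = plan.folds[val_fold]
        train_idx = np.setdiff1d(plan.train_idx, val_idx)
    else:
        rng = np.random.default_rng(seed)
        train_idx, val_idx = _stratified_split(epochs.labels, plan.train_idx, 1 - val_fraction, rng)
    assert np.intersect1d(train_idx, plan.test_idx).size == 0
    assert np.intersect1d(val_idx, plan.test_idx).size == 0
    return fit(network, X[train_idx], y[train_idx], X[val_idx], y[val_idx], hyper, seed=seed)


def repeat_experiment(procedure, n_repeats: int, base_seed: int) -> list:
    """Run ``procedure(seed)`` for seeds ``base_seed + r``; collect results."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    return [procedure(base_seed + r) for r in range(n_repeats)]
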