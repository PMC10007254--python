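"""Split regimes (including the published split constants), fold integrity,
and the training loop's determinism, convergence and learning-rate floor."""

import numpy as np
import pytest

from tests.conftest import tiny_model_spec, tiny_two_class_epochs

from crossphys.evaluation import EvalReport, aggregate
from crossphys.models import TrainHyper, build_model
from crossphys.signal_io import EpochSet
from crossphys.training import (
    SplitPlan,
    make_folds,
    repeat_experiment,
    split_patient_specific,
    split_recordwise,
    split_subjectwise,
    train_model,
)


def _epochs(counts, groups=None, tags=None, seed=0, width=8):
    rng = np.random.default_rng(seed)
    labels = np.concatenate([[s] * n for s, n in counts.items()])
    n = len(labels)
    return EpochSet(
        windows=rng.standard_normal((n, width)).astype(np.float32),
        labels=labels,
        groups=np.asarray(groups) if groups is not None else np.full(n, "g1"),
        dataset_tags=np.asarray(tags) if tags is not None else np.full(n, "d1"),
        fs_hz=1.0,
        window_s=float(width),
    )


class TestSplits:
    def test_ninety_ten_of_198_gives_178_and_20(self):
        ep = _epochs({"interictal": 198, "preictal_20_10": 198})
        plan = split_recordwise(ep, ratio=0.9, seed=0)
        for state in ("interictal", "preictal_20_10"):
            assert (ep.labels[plan.train_idx] == state).sum() == 178
            assert (ep.labels[plan.test_idx] == state).sum() == 20

    def test_eighty_twenty_floor(self):
        ep = _epochs({"a": 16000})
        plan = split_recordwise(ep, ratio=0.8, seed=1)
        assert len(plan.train_idx) == 12800

    def test_union_covers_everything(self):
        ep = _epochs({"a": 57, "b": 43})
        plan = split_recordwise(ep, ratio=0.7, seed=2)
        assert np.array_equal(np.sort(np.concatenate([plan.train_idx, plan.test_idx])), np.arange(100))

    def test_tiny_state_rejected(self):
        ep = _epochs({"a": 50, "b": 1})
        with pytest.raises(ValueError, match="b"):
            split_recordwise(ep, ratio=0.9, seed=0)

    def test_subjectwise_by_tag(self):
        ep = _epochs(
            {"a": 6},
            groups=["s1", "s1", "s1", "s2", "s2", "s2"],
            tags=["A", "A", "A", "B", "B", "B"],
        )
        plan = split_subjectwise(ep, "A", "B")
        assert set(ep.dataset_tags[plan.train_idx]) == {"A"}
        assert set(ep.dataset_tags[plan.test_idx]) == {"B"}
        assert len(plan.train_idx) == 3 and len(plan.test_idx) == 3

    def test_subjectwise_shared_subject_rejected(self):
        ep = _epochs({"a": 4}, groups=["s1", "s1", "s1", "s2"], tags=["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="s1"):
            split_subjectwise(ep, "A", "B")

    def test_subjectwise_missing_tag(self):
        ep = _epochs({"a": 4})
        with pytest.raises(ValueError, match="'B'"):
            split_subjectwise(ep, "d1", "B")

    def test_patient_specific_restricted_to_subject(self):
        ep = _epochs({"a": 20, "b": 20}, groups=["p1"] * 10 + ["p2"] * 10 + ["p1"] * 10 + ["p2"] * 10)
        plan = split_patient_specific(ep, "p1", ratio=0.9, seed=0)
        used = np.concatenate([plan.train_idx, plan.test_idx])
        assert set(ep.groups[used]) == {"p1"}


class TestFolds:
    def test_equal_folds_partition(self):
        ep = _epochs({"a": 50, "b": 50})
        plan = SplitPlan(regime="recordwise", train_idx=np.arange(100), test_idx=np.empty(0, dtype=int))
        plan = make_folds(plan, ep, k=10, seed=0)
        sizes = [len(f) for f in plan.folds]
        assert sizes == [10] * 10
        plan.check_folds()

    def test_stratification_within_one_window(self):
        ep = _epochs({"a": 60, "b": 45})
        plan = SplitPlan(regime="recordwise", train_idx=np.arange(105), test_idx=np.empty(0, dtype=int))
        plan = make_folds(plan, ep, k=5, seed=3)
        for fold in plan.folds:
            a = (ep.labels[fold] == "a").sum()
            assert abs(a - 60 / 5) <= 1

    def test_no_test_leakage_detected(self):
        with pytest.raises(ValueError, match="overlap"):
            SplitPlan(regime="recordwise", train_idx=np.array([0, 1, 2]), test_idx=np.array([2, 3]))

    def test_too_many_folds(self):
        ep = _epochs({"a": 4})
        plan = SplitPlan(regime="recordwise", train_idx=np.arange(4), test_idx=np.empty(0, dtype=int))
        with pytest.raises(ValueError):
            make_folds(plan, ep, k=5)


class TestFit:
    def _setup(self, seed=0):
        ep = tiny_two_class_epochs(seed=seed)
        plan = split_recordwise(ep, ratio=0.8, seed=seed)
        net = build_model(tiny_model_spec(), seed=seed)
        return ep, plan, net

    def test_identical_seed_identical_weights(self):
        hyper = TrainHyper(batch_size=16, lr=1e-3, min_lr=1e-4, max_epochs=3)
        states = []
        for _ in range(2):
            ep, plan, net = self._setup(seed=4)
            train_model(net, ep, plan, hyper, seed=9, label_order=("noise", "tone"))
            states.append(net.get_state())
        assert all(np.array_equal(states[0][k], states[1][k]) for k in states[0])

    def test_learns_separable_task_within_twenty_epochs(self):
        ep, plan, net = self._setup(seed=1)
        hyper = TrainHyper(batch_size=16, lr=1e-3, min_lr=1e-4, max_epochs=20, stop_at_val_accuracy=0.95)
        history = train_model(net, ep, plan, hyper, seed=1, label_order=("noise", "tone"))
        assert max(history["val_acc"]) >= 0.95
        assert len(history["val_acc"]) <= 20

    def test_learning_rate_floored_at_min_lr(self):
        ep, plan, net = self._setup(seed=2)
        hyper = TrainHyper(
            batch_size=16, lr=1e-3, min_lr=5e-4, max_epochs=25, reduce_lr_patience=1
        )
        history = train_model(net, ep, plan, hyper, seed=2, label_order=("noise", "tone"))
        assert min(history["lr"]) >= 5e-4

    def test_history_records_every_epoch(self):
        ep, plan, net = self._setup(seed=3)
        hyper = TrainHyper(batch_size=16, lr=1e-3, min_lr=1e-4, max_epochs=4)
        history = train_model(net, ep, plan, hyper, seed=3, label_order=("noise", "tone"))
        assert {len(v) for v in history.values()} == {4}


class TestRepeatExperiment:
    def _report(self, acc_counts):
        (tp, fn), (fp, tn) = acc_counts
        return EvalReport(confusion=np.array([[tn, fp], [fn, tp]]), label_order=("neg", "pos"))

    def test_single_repeat_zero_std(self):
        reports = repeat_experiment(lambda seed: self._report(((9, 1), (2, 8))), 1, base_seed=0)
        agg = aggregate(reports)
        assert agg["accuracy"]["std"] == 0.0
        assert agg["accuracy"]["single_report"]

    def test_seeds_are_consecutive(self):
        seen = []
        repeat_experiment(lambda seed: seen.append(seed), 3, base_seed=10)
        assert seen == [10, 11, 12]

    def test_aggregation_matches_hand_computation(self):
        reports = [
            self._report(((9, 1), (1, 9))),  # acc 0.9
            self._report(((10, 0), (0, 10))),  # acc 1.0
            self._report(((8, 2), (2, 8))),  # acc 0.8
        ]
        agg = aggregate(reports)
        assert agg["accuracy"]["mean"] == pytest.approx(0.9)
        assert agg["accuracy"]["std"] == pytest.approx(0.1)
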