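"""End-to-end orchestration of the two experiments on synthetic or EDF data.

Experiment 1 (seizure): detrend → 0.5–50 Hz bandpass → GFP → 10-s/8-s
windows → four-state labeling from seizure onsets → per-state balancing →
one of three regimes (recordwise 90:10, subjectwise cross-dataset,
patient-specific pretrain + freeze-n fine-tune) → accuracy/sensitivity/
specificity per preictal band vs interictal.

Experiment 2 (sleep): EEG arm (detrend → 30 Hz lowpass → 30-s/22.5-s windows
→ five-stage labels), ECG arm (detrend → 0.5–40 Hz bandpass → resample to
the 100-Hz model grid → same windowing), and the EEG→ECG transfer arm
(pretrain on EEG, freeze a block prefix, fine-tune on ECG); 80:20 split,
accuracy/κ/macro-F1.

Default problem sizes are desk-scale (a few hundred windows per state, ≤20
epochs) so a full run finishes in minutes on one CPU; the published cohort
sizes (12,222 / 16,000 windows per state, 10/5-fold CV, 5/10 repeats) are
reachable through the same configuration surface.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__
from .evaluation import EvalReport, aggregate, from_predictions
from .models import (
    ModelSpec,
    TrainHyper,
    build_model,
    seizure_hyper,
    seizure_model_spec,
    sleep_hyper,
    sleep_model_spec,
)
from .preprocessing import SEIZURE_BANDPASS, SLEEP_ECG_BANDPASS, SLEEP_EEG_LOWPASS, apply_filter, detrend, gfp
from .segmentation import (
    EPILEPTIC_STATES,
    INTERICTAL,
    PREICTAL_BANDS,
    SEIZURE_WINDOWS,
    SLEEP_WINDOWS,
    balance_states,
    build_state_map,
    label_windows,
    slice_windows,
)
from .signal_io import AASM_STAGES, EpochSet, Recording, concat_epochsets
from .synthetic import HypnogramScenario, SeizureScenario, generate_seizure_recording, generate_sleep_recording
from .training import (
    encode_labels,
    make_folds,
    split_patient_specific,
    split_recordwise,
    split_subjectwise,
    train_model,
)
from .transfer import FreezeSpec, adapt_input, fine_tune

SLEEP_MODEL_FS = 100.0


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything a run needs; defaults are desk-scale synthetic."""

    experiment: str  # "seizure" | "sleep"
    regime: str = "recordwise"  # recordwise | subjectwise | patient_specific | transfer
    data_source: str = "synthetic"
    freeze: FreezeSpec | None = None
    hyper: TrainHyper | None = None
    windows_per_state: int = 200
    repeats: int = 1
    seed: int = 0
    k_folds: int | None = None
    train_ratio: float | None = None  # default 0.9 (seizure) / 0.8 (sleep)
    bands: tuple[str, ...] = PREICTAL_BANDS
    arms: tuple[str, ...] = ("eeg", "ecg", "transfer")
    ecg_train_fraction: float = 1.0
    snr_db: float = 3.0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.experiment not in ("seizure", "sleep"):
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.experiment == "seizure":
            if self.regime not in ("recordwise", "subjectwise", "patient_specific"):
                raise ValueError(f"regime {self.regime!r} invalid for the seizure experiment")
            if self.freeze is not None and self.freeze.mode != "first_n_layers":
                raise ValueError("seizure-experiment freezing uses first_n_layers")
        else:
            if self.freeze is not None and self.freeze.mode != "named_blocks":
                raise ValueError("sleep-experiment freezing uses named_blocks")
        bad = [b for b in self.bands if b not in PREICTAL_BANDS]
        if bad:
            raise ValueError(f"unknown preictal band(s): {bad}")

    @property
    def ratio(self) -> float:
        if self.train_ratio is not None:
            return self.train_ratio
        return 0.9 if self.experiment == "seizure" else 0.8


# ---------------------------------------------------------------------------
# synthetic data preparation (generation → conditioning → labeled windows)
# ---------------------------------------------------------------------------

def seizure_epochset(
    seed: int,
    windows_per_state: int = 200,
    subject_id: str = "subj-01",
    dataset_tag: str = "synthA",
    snr_db: float = 3.0,
) -> EpochSet:
    """One synthetic subject's conditioned, labeled, balanced seizure windows.

    The scenario places a single onset late in the recording so all three
    preictal bands are fully covered and a long interictal stretch precedes
    them (interictal ends 50 min before onset).
    """
    scenario = SeizureScenario(duration_s=6720.0, seizure_onsets_s=(6600.0,), seed=seed, snr_db=snr_db)
    rec = generate_seizure_recording(scenario)
    rec = replace(rec, subject_id=subject_id, source_dataset=dataset_tag)
    conditioned = gfp(apply_filter(detrend(rec), SEIZURE_BANDPASS))
    windows = slice_windows(conditioned, SEIZURE_WINDOWS)
    state_map = build_state_map(scenario.seizure_onsets_s, scenario.duration_s)
    labeled = label_windows(windows, state_map, subject_id=subject_id, dataset_tag=dataset_tag)
    return balance_states(labeled, per_state_n=windows_per_state, seed=seed, expected_states=EPILEPTIC_STATES)


def sleep_epochset(
    modality: str,
    seed: int,
    windows_per_state: int = 200,
    n_epochs: int = 1400,
    subject_id: str = "sleeper-01",
    dataset_tag: str = "synth-sleep",
) -> EpochSet:
    """Conditioned, labeled, balanced sleep windows for one synthetic night.

    EEG: detrend → 30-Hz lowpass. ECG: detrend → 0.5–40-Hz bandpass →
    polyphase resample to the model's 100-Hz grid. Both are then cut with the
    30-s/22.5-s rule and labeled from the hypnogram (windows inside a single
    stage run only).
    """
    scenario = HypnogramScenario(n_epochs=n_epochs, modality=modality, seed=seed)
    rec = generate_sleep_recording(scenario)
    rec = replace(rec, subject_id=subject_id, source_dataset=dataset_tag)
    if modality == "eeg":
        conditioned = apply_filter(detrend(rec), SLEEP_EEG_LOWPASS)
    else:
        conditioned = apply_filter(detrend(rec), SLEEP_ECG_BANDPASS)
        conditioned = adapt_input(conditioned, SLEEP_MODEL_FS)
    windows = slice_windows(conditioned, SLEEP_WINDOWS)
    labeled = label_windows(windows, rec.annotations, subject_id=subject_id, dataset_tag=dataset_tag)
    return balance_states(labeled, per_state_n=windows_per_state, seed=seed, expected_states=AASM_STAGES)


# ---------------------------------------------------------------------------
# experiment 1
# ---------------------------------------------------------------------------

def _band_subset(epochs: EpochSet, band: str) -> EpochSet:
    idx = np.nonzero((epochs.labels == INTERICTAL) | (epochs.labels == band))[0]
    return epochs.subset(idx)


def _evaluate(network, epochs: EpochSet, idx: np.ndarray, label_order, repeat_index, positive_label=None) -> EvalReport:
    X = epochs.windows[idx][:, None, :]
    pred = network.predict(X)
    true = epochs.labels[idx]
    pred_labels = np.array([label_order[i] for i in pred])
    return from_predictions(true, pred_labels, label_order, repeat_index=repeat_index, positive_label=positive_label)


def run_experiment1(config: ExperimentConfig) -> dict[str, list[EvalReport]]:
    """Seizure experiment under the configured regime; reports per preictal band."""
    if config.experiment != "seizure":
        raise ValueError("run_experiment1 needs a seizure config")
    hyper = config.hyper or seizure_hyper(max_epochs=20)
    spec = seizure_model_spec()

    epochs_a = seizure_epochset(config.seed, config.windows_per_state, "subj-01", "synthA", config.snr_db)
    need_b = config.regime in ("subjectwise", "patient_specific")
    pooled = epochs_a
    if need_b:
        epochs_b = seizure_epochset(config.seed + 1000, config.windows_per_state, "subj-02", "synthB", config.snr_db)
        pooled = concat_epochsets([epochs_a, epochs_b])

    results: dict[str, list[EvalReport]] = {band: [] for band in config.bands}
    counts: dict[str, dict] = {}
    for band in config.bands:
        sub = _band_subset(pooled, band)
        label_order = (INTERICTAL, band)
        counts[band] = sub.label_counts
        for r in range(config.repeats):
            run_seed = config.seed + r
            if config.regime == "recordwise":
                plan = split_recordwise(sub, ratio=config.ratio, seed=run_seed)
                if config.k_folds:
                    plan = make_folds(plan, sub, config.k_folds)
                net = build_model(spec, seed=run_seed)
                train_model(net, sub, plan, hyper, seed=run_seed, label_order=label_order)
                report = _evaluate(net, sub, plan.test_idx, label_order, r, positive_label=band)
            elif config.regime == "subjectwise":
                plan = split_subjectwise(sub, "synthA", "synthB")
                net = build_model(spec, seed=run_seed)
                train_model(net, sub, plan, hyper, seed=run_seed, label_order=label_order)
                report = _evaluate(net, sub, plan.test_idx, label_order, r, positive_label=band)
            else:  # patient_specific: pretrain on dataset A, fine-tune on subject in B
                freeze_spec = config.freeze or FreezeSpec(mode="first_n_layers", n=6)
                pre_plan = split_subjectwise(sub, "synthA", "synthB")
                net = build_model(spec, seed=run_seed)
                train_model(net, sub, pre_plan, hyper, seed=run_seed, label_order=label_order)
                target = sub.subset(np.nonzero(sub.groups == "subj-02")[0])
                patient_plan = split_recordwise(target, ratio=config.ratio, seed=run_seed)
                ft_set = target.subset(patient_plan.train_idx)
                fine_tune(net, spec, ft_set, freeze_spec, hyper, seed=run_seed, label_order=label_order)
                report = _evaluate(net, target, patient_plan.test_idx, label_order, r, positive_label=band)
            results[band].append(report)

    if config.output_dir:
        _write_outputs(config, results, counts)
    return results


# ---------------------------------------------------------------------------
# experiment 2
# ---------------------------------------------------------------------------

def _train_sleep_arm(epochs: EpochSet, hyper, seed: int, k_folds: int | None, ratio: float):
    spec = sleep_model_spec()
    plan = split_recordwise(epochs, ratio=ratio, seed=seed)
    if k_folds:
        plan = make_folds(plan, epochs, k_folds)
    net = build_model(spec, seed=seed)
    train_model(net, epochs, plan, hyper, seed=seed, label_order=AASM_STAGES)
    return net, plan


def _reduce_train(epochs: EpochSet, plan, fraction: float, seed: int) -> np.ndarray:
    """Stratified sub-sample of the training indices (the data-scarcity knob)."""
    if fraction >= 1.0:
        return plan.train_idx
    rng = np.random.default_rng(seed)
    keep = []
    labels = epochs.labels
    for state in np.unique(labels[plan.train_idx]):
        idx = plan.train_idx[labels[plan.train_idx] == state]
        n = max(2, int(round(fraction * len(idx))))
        keep.append(rng.choice(idx, size=n, replace=False))
    return np.sort(np.concatenate(keep))


def run_experiment2(config: ExperimentConfig) -> dict[str, list[EvalReport]]:
    """Sleep experiment: EEG arm, ECG arm, and the EEG→ECG transfer arm."""
    if config.experiment != "sleep":
        raise ValueError("run_experiment2 needs a sleep config")
    hyper = config.hyper or sleep_hyper(max_epochs=20)
    spec = sleep_model_spec()
    freeze_spec = config.freeze or FreezeSpec(mode="named_blocks", blocks=("block_1",))

    eeg = sleep_epochset("eeg", config.seed, config.windows_per_state)
    need_ecg = any(a in config.arms for a in ("ecg", "transfer"))
    ecg = sleep_epochset("ecg", config.seed + 2000, config.windows_per_state) if need_ecg else None

    results: dict[str, list[EvalReport]] = {arm: [] for arm in config.arms}
    counts = {"eeg": eeg.label_counts}
    if ecg is not None:
        counts["ecg"] = ecg.label_counts
    for r in range(config.repeats):
        run_seed = config.seed + r
        eeg_net = None
        if "eeg" in config.arms or "transfer" in config.arms:
            eeg_net, eeg_plan = _train_sleep_arm(eeg, hyper, run_seed, config.k_folds, config.ratio)
            if "eeg" in config.arms:
                results["eeg"].append(_evaluate(eeg_net, eeg, eeg_plan.test_idx, AASM_STAGES, r))
        if ecg is not None:
            ecg_plan = split_recordwise(ecg, ratio=config.ratio, seed=run_seed)
            train_idx = _reduce_train(ecg, ecg_plan, config.ecg_train_fraction, run_seed)
            ft_set = ecg.subset(train_idx)
            if "ecg" in config.arms:
                from .training import SplitPlan

                scratch = build_model(spec, seed=run_seed)
                scratch_plan = SplitPlan(  # every reduced window trains; test lives in the full ECG split
                    regime="recordwise",
                    train_idx=np.arange(len(ft_set)),
                    test_idx=np.empty(0, dtype=int),
                    seed=run_seed,
                )
                train_model(scratch, ft_set, scratch_plan, hyper, seed=run_seed,
                            label_order=AASM_STAGES, val_fraction=0.15)
                results["ecg"].append(_evaluate(scratch, ecg, ecg_plan.test_idx, AASM_STAGES, r))
            if "transfer" in config.arms:
                fine_tune(eeg_net, spec, ft_set, freeze_spec, hyper, seed=run_seed, label_order=AASM_STAGES)
                results["transfer"].append(_evaluate(eeg_net, ecg, ecg_plan.test_idx, AASM_STAGES, r))
    if config.output_dir:
        _write_outputs(config, results, counts)
    return results


# ---------------------------------------------------------------------------
# outputs
# ---------------------------------------------------------------------------

def _config_dict(config: ExperimentConfig) -> dict:
    d = asdict(config)
    if config.freeze is not None:
        d["freeze"] = asdict(config.freeze)
    if config.hyper is not None:
        d["hyper"] = asdict(config.hyper)
    return d


def _write_outputs(config: ExperimentConfig, results: dict[str, list[EvalReport]], counts: dict) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "config": _config_dict(config),
        "window_counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    summary = {key: aggregate(reports) for key, reports in results.items() if reports}
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    for key, reports in results.items():
        for rep in reports:
            rep.save_json(out / f"report_{key}_r{rep.repeat_index}.json")
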