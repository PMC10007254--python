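"""Windowing and state labeling: from conditioned signals to labeled epochs.

Experiment 1 (seizure) cuts the GFP trace into 10-s windows with 8-s overlap
and labels each window with one of four epileptic states derived from the
seizure onset times: interictal (≥ 50 min from the next onset, after the
previous seizure) and three 10-min preictal bands ending 10, 20 and 30 min
before onset. Experiment 2 (sleep) cuts single-channel recordings into 30-s
windows with 22.5-s overlap and labels them from the hypnogram, after mapping
the older R&K stage codes onto the five-stage standard (S3 and S4 merge into
N3).

A window receives a label only if it lies entirely inside one state interval
(or one single-stage run of scored epochs); boundary-straddling windows are
dropped to avoid label noise. Per-state counts are then equalized by seeded
undersampling without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import EpochSet, Hypnogram, Recording

#: Epileptic state labels.
INTERICTAL = "interictal"
PREICTAL_BANDS = ("preictal_40_30", "preictal_30_20", "preictal_20_10")
EPILEPTIC_STATES = (INTERICTAL,) + PREICTAL_BANDS

#: Sentinel returned by map_rk_to_aasm for epochs to discard.
DROP = "DROP"

#: R&K → AASM stage mapping; S3 and S4 merge into N3.
_RK_TO_AASM = {
    "W": "W",
    "S1": "N1",
    "S2": "N2",
    "S3": "N3",
    "S4": "N3",
    "REM": "REM",
    "MOVEMENT": DROP,
    "UNKNOWN": DROP,
    # already-AASM codes pass through (the map is idempotent)
    "N1": "N1",
    "N2": "N2",
    "N3": "N3",
}

Interval = tuple[float, float]


@dataclass(frozen=True)
class WindowRule:
    """Fixed-length sliding-window definition; step = window − overlap."""

    window_s: float
    overlap_s: float

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_s < self.window_s):
            raise ValueError(f"need 0 <= overlap ({self.overlap_s}) < window ({self.window_s})")

    @property
    def step_s(self) -> float:
        return self.window_s - self.overlap_s


#: The study's two windowing rules.
SEIZURE_WINDOWS = WindowRule(window_s=10.0, overlap_s=8.0)
SLEEP_WINDOWS = WindowRule(window_s=30.0, overlap_s=22.5)


@dataclass(frozen=True)
class WindowArray:
    """Windows cut from one recording, with absolute start times."""

    windows: np.ndarray  # (n, window_samples)
    start_s: np.ndarray  # (n,)
    fs_hz: float
    window_s: float

    def __len__(self) -> int:
        return self.windows.shape[0]


@dataclass(frozen=True)
class EpilepticStateMap:
    """Half-open second intervals per epileptic state."""

    intervals: dict[str, tuple[Interval, ...]]

    def __getitem__(self, state: str) -> tuple[Interval, ...]:
        return self.intervals[state]


def slice_windows(recording: Recording, rule: WindowRule) -> WindowArray:
    """Cut a single-channel recording into overlapping fixed-length windows.

    Window ``k`` covers ``[k·step, k·step + window)`` seconds; the count is
    ``floor((L − window)/step) + 1``. A signal shorter than one window yields
    an empty array, not an error.
    """
    if recording.n_channels != 1:
        raise ValueError("slice_windows expects a single-channel recording")
    fs = recording.fs_hz
    win_n = int(round(rule.window_s * fs))
    step_n = int(round(rule.step_s * fs))
    x = recording.signal[0]
    if len(x) < win_n:
        return WindowArray(
            windows=np.empty((0, win_n), dtype=np.float32),
            start_s=np.empty(0),
            fs_hz=fs,
            window_s=rule.window_s,
        )
    n = (len(x) - win_n) // step_n + 1
    idx = np.arange(n) * step_n
    windows = np.lib.stride_tricks.sliding_window_view(x, win_n)[idx].copy()
    return WindowArray(
        windows=windows.astype(np.float32),
        start_s=idx / fs,
        fs_hz=fs,
        window_s=rule.window_s,
    )


# ---------------------------------------------------------------------------
# interval arithmetic
# ---------------------------------------------------------------------------

def _clip_interval(iv: Interval, lo: float, hi: float) -> Interval | None:
    a, b = max(iv[0], lo), min(iv[1], hi)
    return (a, b) if b > a else None


def _subtract(base: list[Interval], cuts: list[Interval]) -> list[Interval]:
    """Set difference of interval unions (inputs need not be sorted)."""
    out = list(base)
    for ca, cb in cuts:
        nxt: list[Interval] = []
        for a, b in out:
            if cb <= a or ca >= b:
                nxt.append((a, b))
                continue
            if a < ca:
                nxt.append((a, ca))
            if cb < b:
                nxt.append((cb, b))
        out = nxt
    return sorted(out)


def build_state_map(
    seizure_onsets_s: tuple[float, ...] | list[float],
    duration_s: float,
    seizure_duration_s: float = 0.0,
    interictal_gap_s: float = 3000.0,
    include_tail: bool = False,
) -> EpilepticStateMap:
    """Derive the four epileptic-state interval sets from seizure onsets.

    For each onset ``T``: preictal bands ``[T−2400, T−1800)``,
    ``[T−1800, T−1200)`` and ``[T−1200, T−600)`` seconds (40–30, 30–20 and
    20–10 minutes before onset). Interictal spans run from the previous
    seizure's end (onset + ``seizure_duration_s``) to ``interictal_gap_s``
    (50 min) before the next onset, minus any preictal band, clipped to
    ``[0, duration)``. Onsets too close to the start simply yield truncated
    or empty bands. The stretch after the final onset is post-ictal and is
    excluded unless ``include_tail`` is set.
    """
    onsets = sorted(float(t) for t in seizure_onsets_s)
    bands: dict[str, list[Interval]] = {b: [] for b in PREICTAL_BANDS}
    band_minutes = {"preictal_40_30": (40, 30), "preictal_30_20": (30, 20), "preictal_20_10": (20, 10)}
    all_bands: list[Interval] = []
    for i, onset in enumerate(onsets):
        prev_end = onsets[i - 1] + seizure_duration_s if i > 0 else 0.0
        for band, (lo_min, hi_min) in band_minutes.items():
            iv = _clip_interval(
                (onset - lo_min * 60.0, onset - hi_min * 60.0),
                max(0.0, prev_end),
                duration_s,
            )
            if iv:
                bands[band].append(iv)
                all_bands.append(iv)

    interictal: list[Interval] = []
    for i, onset in enumerate(onsets):
        prev_end = onsets[i - 1] + seizure_duration_s if i > 0 else 0.0
        iv = _clip_interval((prev_end, onset - interictal_gap_s), 0.0, duration_s)
        if iv:
            interictal.append(iv)
    if include_tail and onsets:
        iv = _clip_interval((onsets[-1] + seizure_duration_s, duration_s), 0.0, duration_s)
        if iv:
            interictal.append(iv)
    if not onsets:
        interictal = [(0.0, duration_s)]
    interictal = _subtract(interictal, all_bands)

    intervals = {INTERICTAL: tuple(interictal)}
    intervals.update({b: tuple(sorted(v)) for b, v in bands.items()})
    return EpilepticStateMap(intervals=intervals)


def _hypnogram_intervals(hypnogram: Hypnogram) -> dict[str, list[Interval]]:
    """Merge consecutive same-stage epochs into per-stage interval lists."""
    out: dict[str, list[Interval]] = {}
    run_start = 0
    stages = hypnogram.stages
    for i in range(1, len(stages) + 1):
        if i == len(stages) or stages[i] != stages[run_start]:
            stage = stages[run_start]
            if stage != DROP:
                out.setdefault(stage, []).append(
                    (run_start * hypnogram.epoch_s, i * hypnogram.epoch_s)
                )
            run_start = i
    return out


def label_windows(
    windows: WindowArray,
    states: EpilepticStateMap | Hypnogram,
    subject_id: str = "",
    dataset_tag: str = "",
) -> EpochSet:
    """Assign a state to every window fully contained in one state interval.

    Works for both the seizure state map and a hypnogram (where the interval
    of a label is a maximal run of identically scored 30-s epochs). Windows
    straddling an interval boundary are dropped. Order-independent: the
    result is sorted by window start time.
    """
    if isinstance(states, Hypnogram):
        interval_map = _hypnogram_intervals(states)
    else:
        interval_map = {k: list(v) for k, v in states.intervals.items()}

    starts = windows.start_s
    ends = starts + windows.window_s
    keep_idx: list[np.ndarray] = []
    keep_lab: list[np.ndarray] = []
    eps = 1e-9
    for state, ivs in interval_map.items():
        inside = np.zeros(len(starts), dtype=bool)
        for a, b in ivs:
            inside |= (starts >= a - eps) & (ends <= b + eps)
        if inside.any():
            idx = np.nonzero(inside)[0]
            keep_idx.append(idx)
            keep_lab.append(np.full(len(idx), state, dtype=object))
    if keep_idx:
        idx = np.concatenate(keep_idx)
        lab = np.concatenate(keep_lab).astype(str)
        order = np.argsort(idx, kind="stable")
        idx, lab = idx[order], lab[order]
    else:
        idx = np.empty(0, dtype=int)
        lab = np.empty(0, dtype=str)
    n = len(idx)
    return EpochSet(
        windows=windows.windows[idx] if n else np.empty((0, windows.windows.shape[1]), dtype=np.float32),
        labels=lab,
        groups=np.full(n, subject_id, dtype=object).astype(str),
        dataset_tags=np.full(n, dataset_tag, dtype=object).astype(str),
        fs_hz=windows.fs_hz,
        window_s=windows.window_s,
    )


def map_rk_to_aasm(stage: str) -> str:
    """Map an R&K stage code to the five-stage standard (S3, S4 → N3).

    ``MOVEMENT``/``UNKNOWN`` map to the :data:`DROP` sentinel. Idempotent on
    already-mapped codes; unrecognized codes raise.
    """
    try:
        return _RK_TO_AASM[stage]
    except KeyError:
        raise ValueError(f"unrecognized sleep-stage code: {stage!r}") from None


def map_hypnogram_to_aasm(hypnogram: Hypnogram) -> Hypnogram:
    """Apply :func:`map_rk_to_aasm` to every epoch; DROP epochs survive as
    labels only so the epoch grid stays aligned (label_windows skips them)."""
    mapped = tuple(map_rk_to_aasm(s) for s in hypnogram.stages)
    hyp = Hypnogram.__new__(Hypnogram)
    object.__setattr__(hyp, "stages", mapped)
    object.__setattr__(hyp, "epoch_s", hypnogram.epoch_s)
    return hyp


def balance_states(
    epochs: EpochSet,
    per_state_n: int | None = None,
    seed: int = 0,
    expected_states: tuple[str, ...] | None = None,
) -> EpochSet:
    """Equalize per-state counts by seeded undersampling without replacement.

    ``per_state_n`` defaults to the minimum state count. States listed in
    ``expected_states`` but absent from the data raise an error naming them.
    Provenance fields are preserved; output is ordered by original index.
    """
    counts = epochs.label_counts
    if expected_states:
        missing = [s for s in expected_states if counts.get(s, 0) == 0]
        if missing:
            raise ValueError(f"state(s) with zero windows: {missing}")
    if not counts:
        raise ValueError("cannot balance an empty epoch set")
    n = min(counts.values()) if per_state_n is None else int(per_state_n)
    over = [s for s, c in counts.items() if c < n]
    if over:
        raise ValueError(f"per_state_n={n} exceeds available counts for {over}: {counts}")
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for state in sorted(counts):
        idx = np.nonzero(epochs.labels == state)[0]
        chosen.append(rng.choice(idx, size=n, replace=False))
    idx = np.sort(np.concatenate(chosen))
    return epochs.subset(idx)
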