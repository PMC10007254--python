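"""Recording and epoch containers plus the file formats that carry them.

The two experiments (seizure-state prediction from multichannel EEG, sleep
staging from single-channel EEG or ECG) share one in-memory representation:

* :class:`Recording` — a channels × samples matrix with a sampling rate and an
  annotation track (seizure onset times or a hypnogram).
* :class:`EpochSet` — fixed-length labeled windows cut from recordings, with
  per-window provenance (subject, source dataset).

On disk, recordings travel as plain 16-bit EDF (written here, read back
through :mod:`mne`), hypnograms as a two-column ``onset<TAB>stage`` text
dialect, and epoch sets as a compressed array archive with a JSON metadata
sidecar.  All loaders are pure functions of file content.

Conventions: sample indexing is 0-based and time intervals are half-open
``[start, end)`` in seconds, so they compose with the windowing arithmetic in
:mod:`crossphys.segmentation`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

EPOCHSET_FORMAT_VERSION = 1

#: Sleep-stage vocabulary: current five-stage standard plus the older
#: R&K codes that map onto it (see segmentation.map_rk_to_aasm).
AASM_STAGES = ("W", "N1", "N2", "N3", "REM")
RK_STAGES = ("W", "S1", "S2", "S3", "S4", "REM")


class AnnotationError(ValueError):
    """Raised for malformed annotation tracks (overlaps, gaps, bad codes)."""


@dataclass(frozen=True)
class SeizureAnnotations:
    """Seizure onset timestamps in seconds from recording start."""

    onsets_s: tuple[float, ...]

    def __post_init__(self) -> None:
        onsets = tuple(float(t) for t in self.onsets_s)
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise AnnotationError(f"seizure onsets must be strictly increasing: {onsets}")
        object.__setattr__(self, "onsets_s", onsets)


@dataclass(frozen=True)
class Hypnogram:
    """One sleep-stage label per scored epoch (30 s by default)."""

    stages: tuple[str, ...]
    epoch_s: float = 30.0

    def __post_init__(self) -> None:
        allowed = set(AASM_STAGES) | set(RK_STAGES) | {"MOVEMENT", "UNKNOWN"}
        bad = sorted(set(self.stages) - allowed)
        if bad:
            raise AnnotationError(f"unknown sleep-stage label(s): {bad}")
        object.__setattr__(self, "stages", tuple(self.stages))

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def duration_s(self) -> float:
        return len(self.stages) * self.epoch_s


@dataclass
class Recording:
    """A multichannel sampled signal with its annotation track.

    Parameters
    ----------
    signal
        ``(n_channels, n_samples)`` array. Stored as float32.
    fs_hz
        Sampling rate in samples/second.
    channel_names
        One name per channel.
    annotations
        :class:`SeizureAnnotations`, :class:`Hypnogram`, or ``None``.
    subject_id, source_dataset
        Provenance carried through windowing into :class:`EpochSet`.
    flags
        Non-fatal data-quality warnings attached by producers (e.g. a seizure
        onset too close to the recording start for full preictal coverage).
    """

    signal: np.ndarray
    fs_hz: float
    channel_names: list[str]
    annotations: SeizureAnnotations | Hypnogram | None = None
    subject_id: str = ""
    source_dataset: str = ""
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal)
        if sig.ndim == 1:
            sig = sig[None, :]
        if sig.ndim != 2:
            raise ValueError(f"signal must be 2-D (channels, samples), got shape {sig.shape}")
        self.signal = np.ascontiguousarray(sig, dtype=np.float32)
        if not np.isfinite(self.signal).all():
            raise ValueError("signal contains NaN or Inf samples")
        if self.fs_hz <= 0:
            raise ValueError(f"fs_hz must be positive, got {self.fs_hz}")
        if len(self.channel_names) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.n_channels} channels"
            )
        self._check_annotations()

    def _check_annotations(self) -> None:
        ann = self.annotations
        if isinstance(ann, SeizureAnnotations):
            late = [t for t in ann.onsets_s if not (0 <= t < self.duration_s)]
            if late:
                raise AnnotationError(
                    f"seizure onsets outside [0, {self.duration_s}) s: {late}"
                )
        elif isinstance(ann, Hypnogram):
            if ann.duration_s > self.duration_s + 1e-9:
                raise AnnotationError(
                    f"hypnogram covers {ann.duration_s} s but signal lasts {self.duration_s} s"
                )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def with_signal(self, signal: np.ndarray, channel_names: list[str] | None = None) -> "Recording":
        """Copy of this recording with a new signal matrix (same metadata)."""
        return replace(
            self,
            signal=signal,
            channel_names=list(channel_names) if channel_names is not None else list(self.channel_names),
        )


@dataclass
class EpochSet:
    """Fixed-length single-channel labeled windows with provenance.

    ``windows`` is ``(n_windows, window_samples)``; ``labels``, ``groups``
    (subject ids) and ``dataset_tags`` are parallel string arrays.
    """

    windows: np.ndarray
    labels: np.ndarray
    groups: np.ndarray
    dataset_tags: np.ndarray
    fs_hz: float
    window_s: float

    def __post_init__(self) -> None:
        self.windows = np.ascontiguousarray(np.atleast_2d(self.windows), dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=str)
        self.groups = np.asarray(self.groups, dtype=str)
        self.dataset_tags = np.asarray(self.dataset_tags, dtype=str)
        n = self.windows.shape[0]
        for name in ("labels", "groups", "dataset_tags"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def label_counts(self) -> dict[str, int]:
        values, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(values.tolist(), counts.tolist()))

    def subset(self, idx: np.ndarray) -> "EpochSet":
        idx = np.asarray(idx, dtype=int)
        return EpochSet(
            windows=self.windows[idx],
            labels=self.labels[idx],
            groups=self.groups[idx],
            dataset_tags=self.dataset_tags[idx],
            fs_hz=self.fs_hz,
            window_s=self.window_s,
        )


def concat_epochsets(parts: list[EpochSet]) -> EpochSet:
    """Concatenate epoch sets that share fs and window length."""
    if not parts:
        raise ValueError("no epoch sets to concatenate")
    fs = {p.fs_hz for p in parts}
    ws = {p.window_s for p in parts}
    if len(fs) > 1 or len(ws) > 1:
        raise ValueError(f"incompatible epoch sets: fs {fs}, window_s {ws}")
    return EpochSet(
        windows=np.concatenate([p.windows for p in parts], axis=0),
        labels=np.concatenate([p.labels for p in parts]),
        groups=np.concatenate([p.groups for p in parts]),
        dataset_tags=np.concatenate([p.dataset_tags for p in parts]),
        fs_hz=parts[0].fs_hz,
        window_s=parts[0].window_s,
    )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a plain EDF file (16-bit, 1-s data records, physical unit uV).

    Intended for synthetic fixtures so the real-data and synthetic paths share
    one loader. The sampling rate must be an integer; the signal is
    zero-padded to a whole number of seconds. Annotations are not embedded —
    write them with :func:`write_hypnogram` or keep onset lists alongside.
    """
    path = Path(path)
    fs = recording.fs_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    fs = int(round(fs))
    sig = recording.signal.astype(np.float64)
    n_ch, n_samp = sig.shape
    n_records = int(np.ceil(n_samp / fs))
    padded = np.zeros((n_ch, n_records * fs))
    padded[:, :n_samp] = sig

    phys_min = padded.min(axis=1)
    phys_max = padded.max(axis=1)
    flat = phys_max - phys_min < 1e-12
    phys_max[flat] = phys_min[flat] + 1.0  # avoid zero gain on constant channels
    dig_min, dig_max = -32768, 32767
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((padded - phys_min[:, None]) / gain[:, None] + dig_min).astype("<i2")

    def f(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join(
        [
            f("0", 8),
            f(recording.subject_id or "X", 80),
            f(recording.source_dataset or "X", 80),
            f("01.01.00", 8),
            f("00.00.00", 8),
            f(str(256 * (1 + n_ch)), 8),
            f("", 44),
            f(str(n_records), 8),
            f("1", 8),
            f(str(n_ch), 4),
        ]
    )
    per_sig = b"".join(
        [
            b"".join(f(name, 16) for name in recording.channel_names),
            b"".join(f("", 80) for _ in range(n_ch)),
            b"".join(f("uV", 8) for _ in range(n_ch)),
            b"".join(f(f"{phys_min[i]:.8g}"[:8], 8) for i in range(n_ch)),
            b"".join(f(f"{phys_max[i]:.8g}"[:8], 8) for i in range(n_ch)),
            b"".join(f(str(dig_min), 8) for _ in range(n_ch)),
            b"".join(f(str(dig_max), 8) for _ in range(n_ch)),
            b"".join(f("", 80) for _ in range(n_ch)),
            b"".join(f(str(fs), 8) for _ in range(n_ch)),
            b"".join(f("", 32) for _ in range(n_ch)),
        ]
    )
    # data records: per record, all samples of ch1, then ch2, ...
    records = digital.reshape(n_ch, n_records, fs).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_sig)
        fh.write(records.tobytes())


def load_edf(path: str | Path, channels: list[str] | None = None) -> Recording:
    """Read an EDF file into a :class:`Recording` (signal in microvolts).

    Mixed-rate EDF files are handled by selecting the requested ``channels``
    only; without a selection all channels must share one sampling rate.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(
            str(path),
            include=channels if channels else None,
            preload=True,
            verbose="error",
        )
    if channels:
        missing = [c for c in channels if c not in raw.ch_names]
        if missing:
            raise KeyError(f"channel(s) {missing} not present in {path.name}; has {raw.ch_names}")
        raw = raw.pick(channels)
    if len(raw.ch_names) == 0:
        raise ValueError(f"{path.name} contains no channels")
    data = raw.get_data() * 1e6  # mne scales EDF uV channels to volts
    return Recording(
        signal=data,
        fs_hz=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        subject_id=path.stem,
        source_dataset="",
    )


# ---------------------------------------------------------------------------
# Hypnogram text dialect
# ---------------------------------------------------------------------------

def write_hypnogram(hypnogram: Hypnogram, path: str | Path) -> None:
    """Write the two-column ``onset_s<TAB>stage`` run-length dialect.

    Each line marks the onset of a stage run; the stage holds until the next
    onset. A final ``END`` sentinel carries the total duration.
    """
    lines = []
    t = 0.0
    prev: str | None = None
    for stage in hypnogram.stages:
        if stage != prev:
            lines.append(f"{t:g}\t{stage}")
            prev = stage
        t += hypnogram.epoch_s
    lines.append(f"{t:g}\tEND")
    Path(path).write_text("\n".join(lines) + "\n")


def load_hypnogram(path: str | Path, epoch_s: float = 30.0) -> Hypnogram:
    """Read the two-column text dialect back into a per-epoch stage sequence.

    Stage runs longer than one epoch expand to repeated epochs. Onsets must be
    strictly increasing multiples of ``epoch_s``; violations are reported with
    the offending intervals.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    entries: list[tuple[float, str]] = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise AnnotationError(f"{path.name}:{ln}: expected 'onset stage', got {line!r}")
        entries.append((float(parts[0]), parts[1]))
    if not entries or entries[-1][1] != "END":
        raise AnnotationError(f"{path.name}: missing END sentinel with total duration")
    bad: list[str] = []
    for (t0, s0), (t1, _) in zip(entries, entries[1:]):
        if t1 <= t0:
            bad.append(f"[{t0}, {t1}) ({s0}): non-increasing onset")
        if abs(t0 / epoch_s - round(t0 / epoch_s)) > 1e-9:
            bad.append(f"[{t0}, {t1}) ({s0}): onset not aligned to {epoch_s}-s epochs")
    if bad:
        raise AnnotationError(f"{path.name}: malformed annotation intervals: " + "; ".join(bad))
    stages: list[str] = []
    for (t0, stage), (t1, _) in zip(entries, entries[1:]):
        stages.extend([stage] * int(round((t1 - t0) / epoch_s)))
    return Hypnogram(stages=tuple(stages), epoch_s=epoch_s)


# ---------------------------------------------------------------------------
# EpochSet fixture container
# ---------------------------------------------------------------------------

def save_epochset(epochs: EpochSet, path: str | Path) -> None:
    """Lossless epoch-set container: .npz archive + .json metadata sidecar."""
    path = Path(path)
    np.savez_compressed(
        path.with_suffix(".npz"),
        windows=epochs.windows,
        labels=epochs.labels,
        groups=epochs.groups,
        dataset_tags=epochs.dataset_tags,
    )
    meta = {
        "format_version": EPOCHSET_FORMAT_VERSION,
        "fs_hz": epochs.fs_hz,
        "window_s": epochs.window_s,
        "n_windows": len(epochs),
        "label_counts": epochs.label_counts,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")


def load_epochset(path: str | Path) -> EpochSet:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    version = meta.get("format_version")
    if version != EPOCHSET_FORMAT_VERSION:
        raise ValueError(
            f"epoch-set container version mismatch: file has {version}, "
            f"reader supports {EPOCHSET_FORMAT_VERSION}"
        )
    with np.load(path.with_suffix(".npz"), allow_pickle=False) as archive:
        return EpochSet(
            windows=archive["windows"],
            labels=archive["labels"],
            groups=archive["groups"],
            dataset_tags=archive["dataset_tags"],
            fs_hz=float(meta["fs_hz"]),
            window_s=float(meta["window_s"]),
        )
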