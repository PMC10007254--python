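"""Synthetic EEG/ECG recordings with class-dependent, learnable structure.

Real seizure and polysomnography corpora are multi-gigabyte downloads; the
analysis pipeline is therefore exercised on generated recordings that carry
the statistical structure the method assumes:

* **Seizure EEG** — 29 channels at 512 Hz. The interictal background is
  1/f ("pink") noise; each preictal band adds a band-limited oscillation with
  a distinct center frequency (4, 8 and 16 Hz for the 40–30, 30–20 and 20–10
  minute bands) projected through a random dipolar channel topography, so the
  class structure survives the global-field-power reduction and is separable
  by a small CNN.
* **Sleep EEG** — single channel at 100 Hz; each 30-s epoch carries the
  stage's dominant rhythm (W: 8–12 Hz alpha; N1: 4–7 Hz theta; N2: theta plus
  12–14 Hz spindle bursts; N3: 0.5–2 Hz high-amplitude delta; REM: mixed
  4–8 Hz at low amplitude).
* **Sleep ECG** — single lead at 256 Hz; a QRS-like template train whose mean
  rate and beat-to-beat variability depend on stage (W 75±5, N1 70±4,
  N2 65±3, N3 58±2, REM 72±8 beats/min), with respiratory sinus arrhythmia
  scaled to the same variability.

Hypnograms come from a first-order Markov chain with a diagonally dominant
transition matrix. Everything is deterministic given the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import AASM_STAGES, Hypnogram, Recording, SeizureAnnotations

#: Center frequency (Hz) of the oscillation added in each preictal band.
PREICTAL_BAND_HZ = {
    "preictal_40_30": 4.0,
    "preictal_30_20": 8.0,
    "preictal_20_10": 16.0,
}

#: Stage-dependent heart rate, mean ± sd in beats/min.
ECG_STAGE_BPM = {
    "W": (75.0, 5.0),
    "N1": (70.0, 4.0),
    "N2": (65.0, 3.0),
    "N3": (58.0, 2.0),
    "REM": (72.0, 8.0),
}

#: Dominant-rhythm band (Hz) per sleep stage for the EEG generator.
EEG_STAGE_BAND = {
    "W": (8.0, 12.0),
    "N1": (4.0, 7.0),
    "N2": (4.0, 7.0),
    "N3": (0.5, 2.0),
    "REM": (4.0, 8.0),
}

#: Default hypnogram transition matrix, rows/cols in AASM_STAGES order.
#: Diagonally dominant; off-diagonal mass follows plausible stage successions
#: (W→N1, N1→N2, N2→{N3, REM}, N3→N2, REM→{N1, W}).
HYPNOGRAM_TRANSITIONS = np.array(
    [
        # W     N1    N2    N3    REM
        [0.80, 0.15, 0.02, 0.01, 0.02],  # W
        [0.10, 0.60, 0.25, 0.01, 0.04],  # N1
        [0.03, 0.05, 0.75, 0.12, 0.05],  # N2
        [0.01, 0.01, 0.18, 0.78, 0.02],  # N3
        [0.05, 0.10, 0.05, 0.01, 0.79],  # REM
    ]
)

#: Preictal coverage horizon: an onset closer than this to recording start
#: cannot carry all three 10-min preictal bands.
FULL_PREICTAL_S = 2400.0


@dataclass(frozen=True)
class SeizureScenario:
    """Layout of a synthetic multichannel seizure recording."""

    duration_s: float
    seizure_onsets_s: tuple[float, ...]
    n_channels: int = 29
    fs_hz: float = 512.0
    snr_db: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        onsets = tuple(float(t) for t in self.seizure_onsets_s)
        object.__setattr__(self, "seizure_onsets_s", onsets)
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError(f"onsets must be strictly increasing: {onsets}")
        if onsets and not (0 <= onsets[0] and onsets[-1] < self.duration_s):
            raise ValueError(f"onsets must lie in [0, {self.duration_s}): {onsets}")
        if self.n_channels < 2:
            raise ValueError("seizure scenarios need at least 2 channels")
        if self.duration_s <= 0 or self.fs_hz <= 0:
            raise ValueError("duration_s and fs_hz must be positive")


@dataclass(frozen=True)
class HypnogramScenario:
    """Layout of a synthetic single-channel sleep recording."""

    n_epochs: int
    stage_labels: tuple[str, ...] | None = None
    modality: str = "eeg"
    epoch_s: float = 30.0
    fs_hz: float | None = None
    snr_db: float = 3.0
    ecg_noise_std: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if self.modality not in ("eeg", "ecg"):
            raise ValueError(f"modality must be 'eeg' or 'ecg', got {self.modality!r}")
        if self.fs_hz is None:
            object.__setattr__(self, "fs_hz", 100.0 if self.modality == "eeg" else 256.0)
        if self.stage_labels is not None:
            labels = tuple(self.stage_labels)
            if len(labels) != self.n_epochs:
                raise ValueError(
                    f"{len(labels)} stage labels for {self.n_epochs} epochs"
                )
            object.__setattr__(self, "stage_labels", labels)


def pink_noise(rng: np.random.Generator, n_samples: int, n_channels: int = 1) -> np.ndarray:
    """1/f-amplitude noise, unit standard deviation per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    spectrum = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    out = np.fft.irfft(spectrum * scale, n=n_samples, axis=1)
    out /= out.std(axis=1, keepdims=True)
    return out


def _tone_amplitude(snr_db: float) -> float:
    """Sine amplitude giving the requested tone-power / unit-noise-power ratio."""
    return float(np.sqrt(2.0 * 10.0 ** (snr_db / 10.0)))


def generate_seizure_recording(scenario: SeizureScenario) -> Recording:
    """Synthesize a 29-channel seizure recording with labeled-state structure.

    Background: independent pink noise per channel (unit std) plus a little
    white noise. Each preictal band of each seizure adds its center-frequency
    oscillation through a zero-mean random topography (unit RMS across
    channels), so across-channel variance — hence GFP — rises at the band
    frequency while the common-mode average does not.

    Onsets closer than 40 min to the recording start get a ``flags`` entry on
    the returned recording (truncated preictal coverage), not an error.
    """
    rng = np.random.default_rng(scenario.seed)
    fs = scenario.fs_hz
    n_samples = int(round(scenario.duration_s * fs))
    sig = pink_noise(rng, n_samples, scenario.n_channels)
    sig += 0.1 * rng.standard_normal(sig.shape)

    amp = _tone_amplitude(scenario.snr_db)
    t = np.arange(n_samples) / fs
    # one fixed topography per preictal band, shared across seizures
    topographies = {}
    for band in PREICTAL_BAND_HZ:
        g = rng.standard_normal(scenario.n_channels)
        g -= g.mean()
        g /= np.sqrt(np.mean(g**2))
        topographies[band] = g

    flags: list[str] = []
    for onset in scenario.seizure_onsets_s:
        if onset < FULL_PREICTAL_S:
            flags.append(f"truncated_preictal_coverage:onset={onset:g}s")
        for band, f_hz in PREICTAL_BAND_HZ.items():
            lo_min, hi_min = {"preictal_40_30": (40, 30), "preictal_30_20": (30, 20), "preictal_20_10": (20, 10)}[band]
            a = max(onset - lo_min * 60.0, 0.0)
            b = max(onset - hi_min * 60.0, 0.0)
            if b <= a:
                continue
            i0, i1 = int(round(a * fs)), int(round(b * fs))
            phase = rng.uniform(0, 2 * np.pi)
            osc = amp * np.sin(2 * np.pi * f_hz * t[i0:i1] + phase)
            sig[:, i0:i1] += topographies[band][:, None] * osc[None, :]

    names = [f"EEG{i + 1:02d}" for i in range(scenario.n_channels)]
    return Recording(
        signal=sig,
        fs_hz=fs,
        channel_names=names,
        annotations=SeizureAnnotations(scenario.seizure_onsets_s),
        subject_id=f"synthetic-seizure-{scenario.seed}",
        source_dataset="synthetic",
        flags=tuple(flags),
    )


def generate_hypnogram(n_epochs: int, seed: int) -> tuple[str, ...]:
    """Sample a stage sequence from the first-order Markov chain.

    Starts in W. For ``n_epochs >= 50`` the returned sequence is guaranteed to
    visit all five stages: the chain is redrawn with derived seeds until it
    does (deterministic given ``seed``; with the default diagonally dominant
    matrix a redraw is rarely needed).
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    P = HYPNOGRAM_TRANSITIONS
    cum = np.cumsum(P, axis=1)
    for attempt in range(1000):
        rng = np.random.default_rng((seed, attempt))
        states = np.empty(n_epochs, dtype=int)
        states[0] = 0  # W
        u = rng.random(n_epochs)
        for i in range(1, n_epochs):
            states[i] = np.searchsorted(cum[states[i - 1]], u[i])
        if n_epochs < 50 or len(np.unique(states)) == 5:
            return tuple(AASM_STAGES[s] for s in states)
    raise RuntimeError("failed to sample a hypnogram visiting all stages")  # pragma: no cover


def _eeg_epoch(rng: np.random.Generator, stage: str, n: int, fs: float, amp: float) -> np.ndarray:
    """Stage-dependent rhythm content of one sleep-EEG epoch (noise added later)."""
    t = np.arange(n) / fs
    lo, hi = EEG_STAGE_BAND[stage]
    f = rng.uniform(lo, hi)
    phase = rng.uniform(0, 2 * np.pi)
    if stage == "N3":
        return 3.0 * amp * np.sin(2 * np.pi * f * t + phase)
    if stage == "REM":
        f2 = rng.uniform(lo, hi)
        ph2 = rng.uniform(0, 2 * np.pi)
        return 0.6 * amp * (np.sin(2 * np.pi * f * t + phase) + np.sin(2 * np.pi * f2 * t + ph2))
    x = amp * np.sin(2 * np.pi * f * t + phase)
    if stage == "N2":
        # 12-14 Hz spindle bursts: 1-s Hann-windowed packets every ~3 s
        spindle_f = rng.uniform(12.0, 14.0)
        burst_len = int(fs)
        start = rng.uniform(0.0, 2.0)
        while start + 1.0 < n / fs:
            i0 = int(start * fs)
            win = np.hanning(burst_len)
            tt = t[i0 : i0 + burst_len]
            x[i0 : i0 + burst_len] += 1.5 * amp * win[: len(tt)] * np.sin(2 * np.pi * spindle_f * tt)
            start += rng.uniform(2.5, 3.5)
    return x


def _qrs_template(fs: float) -> np.ndarray:
    """A schematic P-QRS-T beat, R peak amplitude 1, ~0.7 s support."""
    t = np.arange(int(0.7 * fs)) / fs - 0.25
    def g(center, width, amp):
        return amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    return (
        g(-0.18, 0.025, 0.15)   # P
        + g(-0.035, 0.008, -0.15)  # Q
        + g(0.0, 0.012, 1.0)    # R
        + g(0.035, 0.008, -0.25)  # S
        + g(0.22, 0.05, 0.35)   # T
    )


def _ecg_signal(
    rng: np.random.Generator,
    stages: tuple[str, ...],
    epoch_s: float,
    fs: float,
    noise_std: float,
) -> np.ndarray:
    """QRS template train following the hypnogram's stage-dependent rate."""
    duration = len(stages) * epoch_s
    n = int(round(duration * fs))
    sig = np.zeros(n)
    template = _qrs_template(fs)
    half = len(template) // 2

    t_beat = float(rng.uniform(0.0, 0.5))
    while t_beat < duration:
        stage = stages[min(int(t_beat / epoch_s), len(stages) - 1)]
        mean_bpm, sd_bpm = ECG_STAGE_BPM[stage]
        # respiratory sinus arrhythmia at ~0.25 Hz, depth tied to stage sd
        bpm = (
            mean_bpm
            + sd_bpm * rng.standard_normal()
            + sd_bpm * np.sin(2 * np.pi * 0.25 * t_beat)
        )
        rr = float(np.clip(60.0 / max(bpm, 20.0), 0.3, 2.0))
        center = int(round(t_beat * fs))
        i0, i1 = center - half, center - half + len(template)
        s0, s1 = max(i0, 0), min(i1, n)
        if s0 < s1:
            sig[s0:s1] += template[s0 - i0 : s1 - i0]
        t_beat += rr
    if noise_std > 0:
        sig += noise_std * (0.7 * pink_noise(rng, n)[0] + 0.3 * rng.standard_normal(n))
    return sig


def generate_sleep_recording(scenario: HypnogramScenario) -> Recording:
    """Synthesize a single-channel sleep recording with its hypnogram.

    EEG modality: per-epoch stage rhythms on a pink-noise background at the
    scenario's SNR. ECG modality: QRS template train with stage-dependent
    rate and variability plus low-level broadband noise. The hypnogram is
    attached as the recording's annotation track.
    """
    rng = np.random.default_rng(scenario.seed)
    stages = scenario.stage_labels
    if stages is None:
        stages = generate_hypnogram(scenario.n_epochs, scenario.seed)
    unknown = sorted(set(stages) - set(AASM_STAGES))
    if unknown:
        raise ValueError(f"unknown sleep stage label(s): {unknown}")

    fs = float(scenario.fs_hz)
    epoch_n = int(round(scenario.epoch_s * fs))
    n = epoch_n * scenario.n_epochs

    if scenario.modality == "eeg":
        sig = pink_noise(rng, n)[0]
        amp = _tone_amplitude(scenario.snr_db)
        for k, stage in enumerate(stages):
            sig[k * epoch_n : (k + 1) * epoch_n] += _eeg_epoch(rng, stage, epoch_n, fs, amp)
        channel = "Fpz-Cz"
    else:
        sig = _ecg_signal(rng, stages, scenario.epoch_s, fs, scenario.ecg_noise_std)
        channel = "ECG"

    return Recording(
        signal=sig[None, :],
        fs_hz=fs,
        channel_names=[channel],
        annotations=Hypnogram(stages=stages, epoch_s=scenario.epoch_s),
        subject_id=f"synthetic-sleep-{scenario.modality}-{scenario.seed}",
        source_dataset="synthetic",
    )
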