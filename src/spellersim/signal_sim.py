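"""Synthetic EEG generation for the row-column P300 speller.

A simulated participant is described by a :class:`SubjectModel`: a
per-channel P300 template (Gaussian bump peaking 250-500 ms after an
attended flash, largest over parieto-occipital sites) superimposed
additively on background noise.  Because the 0-800 ms analysis window is
much longer than the 224 ms stimulus onset asynchrony, responses to
consecutive flashes overlap; the generator therefore builds a continuous
multichannel stream per selection and epochs are cut from it afterwards.

All randomness flows from integer seeds through named
``numpy.random.SeedSequence`` substreams (noise, jitter, subject), so a
fixed (subject, schedule) pair reproduces the signal bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .rcp_engine import FlashSchedule, make_flash_schedule

#: electrode montage of the recording (10/20 positions)
CHANNELS: tuple[str, ...] = ("Fz", "Cz", "Pz", "Oz", "P3", "P4", "PO7", "PO8")

#: relative P300 topography, peak microvolts per channel at difficulty 0
_BASE_AMPLITUDE_UV = {
    "Fz": 2.0, "Cz": 3.0, "Pz": 5.0, "Oz": 4.0,
    "P3": 3.5, "P4": 3.5, "PO7": 5.0, "PO8": 5.0,
}

_NOISE_SIGMA_MAX_UV = 150.0   # broadband sigma at difficulty 1 (pre-filter)
_NOISE_EXPONENT = 3           # sigma grows as difficulty**3 (see docs/methods.md)
_AMPLITUDE_FLOOR = 0.2        # amplitude scale left at difficulty 1


@dataclass(frozen=True)
class TimingConfig:
    """Stimulation and epoching timing of the paradigm.

    Defaults mirror the study system: 250 Hz sampling, 192 ms flashes at a
    224 ms SOA, 0-800 ms analysis window (200 samples).
    """

    sample_rate_hz: float = 250.0
    stimulus_duration_s: float = 0.192
    soa_s: float = 0.224
    epoch_window_s: tuple[float, float] = (0.0, 0.8)
    inter_selection_pause_s: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.stimulus_duration_s <= 0 or self.soa_s <= 0:
            raise ValueError("stimulus timing must be positive")
        if self.soa_s < self.stimulus_duration_s:
            raise ValueError("soa_s must be >= stimulus_duration_s")
        if self.inter_selection_pause_s < 0:
            raise ValueError("inter_selection_pause_s must be >= 0")
        w0, w1 = self.epoch_window_s
        if w1 <= w0:
            raise ValueError("epoch window must have positive length")

    @property
    def soa_samples(self) -> int:
        return round(self.soa_s * self.sample_rate_hz)

    @property
    def epoch_samples(self) -> int:
        w0, w1 = self.epoch_window_s
        return round((w1 - w0) * self.sample_rate_hz)

    @property
    def epoch_offset_samples(self) -> int:
        return round(self.epoch_window_s[0] * self.sample_rate_hz)


@dataclass(frozen=True)
class SubjectModel:
    """Generative parameters of one simulated participant."""

    seed: int
    p300_amplitude_uv: tuple[float, ...]   # per channel, order of CHANNELS
    p300_latency_s: float
    latency_jitter_s: float
    template_width_s: float
    noise_sigma_uv: float
    noise_spectrum: str = "white"          # "white" | "one_over_f"

    def __post_init__(self) -> None:
        if len(self.p300_amplitude_uv) != len(CHANNELS):
            raise ValueError("one amplitude per channel required")
        if any(a < 0 for a in self.p300_amplitude_uv):
            raise ValueError("amplitudes must be >= 0")
        if not 0.25 <= self.p300_latency_s <= 0.5:
            raise ValueError("p300_latency_s must lie in [0.25, 0.5]")
        if self.latency_jitter_s < 0:
            raise ValueError("latency_jitter_s must be >= 0")
        if self.template_width_s <= 0:
            raise ValueError("template_width_s must be positive")
        if self.latency_jitter_s >= self.template_width_s:
            raise ValueError("jitter must be smaller than template width")
        if self.noise_sigma_uv < 0:
            raise ValueError("noise_sigma_uv must be >= 0")
        if self.noise_spectrum not in ("white", "one_over_f"):
            raise ValueError("noise_spectrum must be 'white' or 'one_over_f'")


@dataclass(frozen=True)
class StimulusEvent:
    """One row/column flash: onset sample, stimulus id 0-13, target flag."""

    onset_sample: int
    stimulus_id: int
    is_target: bool

    def __post_init__(self) -> None:
        if self.onset_sample < 0:
            raise ValueError("onset_sample must be >= 0")
        if not 0 <= self.stimulus_id <= 13:
            raise ValueError("stimulus_id must be in 0..13")


@dataclass(frozen=True)
class SelectionRecord:
    """Bookkeeping for one selection inside an :class:`EpochSet`."""

    attended_item: tuple[int, int]
    schedule: FlashSchedule
    event_start: int   # index of its first event in the EpochSet


@dataclass
class EpochSet:
    """Stimulus-locked windows: ``epochs[i]`` is channels x samples."""

    epochs: np.ndarray                     # (n_events, n_channels, n_samples)
    events: list[StimulusEvent]
    channel_names: tuple[str, ...] = CHANNELS
    selections: list[SelectionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_events, n_channels, n_samples)")
        if len(self.events) != self.epochs.shape[0]:
            raise ValueError("one epoch per event required")
        if self.epochs.shape[0] and self.epochs.shape[1] != len(self.channel_names):
            raise ValueError("channel count mismatch")

    def __len__(self) -> int:
        return self.epochs.shape[0]

    @property
    def labels(self) -> np.ndarray:
        """Boolean target labels, one per epoch."""
        return np.array([e.is_target for e in self.events], dtype=bool)

    def concat(self, other: "EpochSet") -> "EpochSet":
        if self.channel_names != other.channel_names:
            raise ValueError("channel montage mismatch")
        offset = len(self)
        sels = self.selections + [
            replace(s, event_start=s.event_start + offset) for s in other.selections
        ]
        return EpochSet(
            np.concatenate([self.epochs, other.epochs]) if len(other) else self.epochs,
            self.events + other.events,
            self.channel_names,
            sels,
        )


def make_subject_model(seed: int, difficulty: float) -> SubjectModel:
    """Draw a simulated participant.

    ``difficulty`` in [0, 1] monotonically increases the noise/amplitude
    ratio: 0 is a noiseless idealized recording, 1 is chance-level control.
    Deterministic for a fixed seed.
    """
    if not 0.0 <= difficulty <= 1.0:
        raise ValueError("difficulty must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5AB]))
    return _build_subject(seed, difficulty, rng)


def _build_subject(seed: int, difficulty: float, rng: np.random.Generator) -> SubjectModel:
    global_gain = rng.uniform(0.9, 1.1)
    per_channel = rng.uniform(0.95, 1.05, size=len(CHANNELS))
    amp_scale = 1.0 - (1.0 - _AMPLITUDE_FLOOR) * difficulty
    amps = tuple(
        _BASE_AMPLITUDE_UV[ch] * global_gain * g * amp_scale
        for ch, g in zip(CHANNELS, per_channel)
    )
    latency = float(rng.uniform(0.30, 0.40))
    return SubjectModel(
        seed=int(seed),
        p300_amplitude_uv=amps,
        p300_latency_s=latency,
        latency_jitter_s=0.005 + 0.025 * difficulty,
        template_width_s=0.060,
        noise_sigma_uv=_NOISE_SIGMA_MAX_UV * difficulty**_NOISE_EXPONENT,
        noise_spectrum="white",
    )


def _one_over_f_noise(rng: np.random.Generator, shape: tuple[int, ...],
                      sigma: float) -> np.ndarray:
    """Gaussian noise with ~1/f amplitude spectrum, unit-calibrated sigma."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1], d=1.0)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz] / freqs[nz][0])
    shaped = np.fft.irfft(spec * scale, n=shape[-1], axis=-1)
    std = shaped.std()
    return shaped * (sigma / std) if std > 0 else shaped


def target_stimulus_ids(attended_item: tuple[int, int]) -> tuple[int, int]:
    """Stimulus ids (row, 7+column) carrying the attended cell."""
    row, col = attended_item
    if not (0 <= row < 7 and 0 <= col < 7):
        raise ValueError("attended_item must lie inside the 7x7 grid")
    return row, 7 + col


def generate_selection_stream(
    subject: SubjectModel,
    schedule: FlashSchedule,
    attended_item: tuple[int, int] | None,
    timing: TimingConfig = TimingConfig(),
) -> tuple[np.ndarray, list[StimulusEvent]]:
    """Continuous 8-channel signal for one selection plus its flash events.

    Every flash of the attended row or column adds the subject's P300
    template (jittered in latency) to all channels; non-target flashes add
    nothing.  ``attended_item=None`` models a non-attending user: pure
    noise, all events non-target.
    """
    ids = np.asarray(schedule.stimulus_ids)
    if ids.size == 0:
        raise ValueError("empty flash schedule")
    targets = set(target_stimulus_ids(attended_item)) if attended_item is not None else set()

    soa = timing.soa_samples
    n_samples = (ids.size - 1) * soa + timing.epoch_samples + timing.epoch_offset_samples
    n_ch = len(CHANNELS)

    ss = np.random.SeedSequence([subject.seed, schedule.seed, ids.size])
    noise_rng, jitter_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    if subject.noise_sigma_uv > 0:
        if subject.noise_spectrum == "one_over_f":
            signal = _one_over_f_noise(noise_rng, (n_ch, n_samples), subject.noise_sigma_uv)
        else:
            signal = noise_rng.normal(0.0, subject.noise_sigma_uv, (n_ch, n_samples))
    else:
        signal = np.zeros((n_ch, n_samples))

    fs = timing.sample_rate_hz
    amps = np.asarray(subject.p300_amplitude_uv)
    width = subject.template_width_s * fs
    events: list[StimulusEvent] = []
    for i, sid in enumerate(ids):
        onset = i * soa
        is_target = int(sid) in targets
        events.append(StimulusEvent(onset, int(sid), is_target))
        if not is_target:
            continue
        jitter = jitter_rng.uniform(-subject.latency_jitter_s, subject.latency_jitter_s)
        peak = onset + (subject.p300_latency_s + jitter) * fs
        lo = max(0, int(peak - 4 * width))
        hi = min(n_samples, int(peak + 4 * width) + 1)
        t = np.arange(lo, hi)
        bump = np.exp(-0.5 * ((t - peak) / width) ** 2)
        signal[:, lo:hi] += amps[:, None] * bump[None, :]
    return signal, events


def generate_calibration_run(
    subject: SubjectModel,
    word: str,
    n_seq: int,
    timing: TimingConfig,
    layout,
    filter_chain=None,
    run_seed: int | None = None,
) -> EpochSet:
    """Labeled epochs of a no-feedback calibration block.

    One selection per character of ``word``; each selection flashes every
    row and column ``n_seq`` times (14 x n_seq events, 2 x n_seq targets).
    When ``filter_chain`` is given, each selection's continuous stream is
    filtered (causally) before epoching, mirroring the online pipeline.
    ``layout`` is the Spelling menu used to locate each character.
    """
    from .preprocessing import apply_filter_chain, extract_epochs

    if n_seq < 1:
        raise ValueError("n_seq must be >= 1")
    base = subject.seed if run_seed is None else run_seed
    out: EpochSet | None = None
    for i, char in enumerate(word):
        pos = layout.find(char)
        if pos is None:
            raise ValueError(f"character {char!r} not present in the spelling layout")
        schedule = make_flash_schedule(n_seq, seed=int(base) * 1000 + i)
        signal, events = generate_selection_stream(subject, schedule, pos, timing)
        if filter_chain is not None:
            signal = apply_filter_chain(filter_chain, signal)
        es = extract_epochs(signal, events, timing)
        es.selections = [SelectionRecord(pos, schedule, 0)]
        out = es if out is None else out.concat(es)
    assert out is not None
    return out


# ---------------------------------------------------------------------------
# CSV / JSON epoch interchange (long format + sidecar with events and timing)

def write_epochs_csv(epoch_set: EpochSet, csv_path, sidecar_path) -> None:
    n, c, s = epoch_set.epochs.shape
    df = pd.DataFrame({
        "epoch_id": np.repeat(np.arange(n), c * s),
        "channel": np.tile(np.repeat(list(epoch_set.channel_names), s), n),
        "sample_index": np.tile(np.arange(s), n * c),
        "value_uv": epoch_set.epochs.ravel(),
    })
    df.to_csv(csv_path, index=False)
    sidecar = {
        "channel_names": list(epoch_set.channel_names),
        "events": [
            {"onset_sample": e.onset_sample, "stimulus_id": e.stimulus_id,
             "is_target": bool(e.is_target)}
            for e in epoch_set.events
        ],
    }
    with open(sidecar_path, "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1)


def read_epochs_csv(csv_path, sidecar_path) -> EpochSet:
    with open(sidecar_path, encoding="utf-8") as fh:
        sidecar = json.load(fh)
    channels = tuple(sidecar["channel_names"])
    events = [StimulusEvent(e["onset_sample"], e["stimulus_id"], e["is_target"])
              for e in sidecar["events"]]
    df = pd.read_csv(csv_path)
    n = df["epoch_id"].nunique()
    s = df["sample_index"].nunique()
    order = {ch: i for i, ch in enumerate(channels)}
    df = df.sort_values(
        ["epoch_id", "channel", "sample_index"],
        key=lambda col: col.map(order) if col.name == "channel" else col,
        kind="stable",
    )
    epochs = df["value_uv"].to_numpy().reshape(n, len(channels), s)
    return EpochSet(epochs, events, channels)
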