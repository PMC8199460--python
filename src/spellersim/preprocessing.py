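"""Online filter chain and epoch extraction.

The chain reproduces the acquisition pipeline of the speller: a 0.1-9 Hz
band-pass (first-order IIR high-pass plus second-order Butterworth
low-pass) and a 50 Hz Chebyshev notch.  Filtering is causal (single
forward pass) by default, as in the online system; a zero-phase flag is
available for offline re-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_sim import EpochSet, StimulusEvent, TimingConfig


@dataclass(frozen=True)
class FilterChain:
    """Second-order sections of the three stages, in application order."""

    highpass_sos: np.ndarray
    lowpass_sos: np.ndarray
    notch_sos: np.ndarray
    sample_rate_hz: float

    @property
    def sos(self) -> np.ndarray:
        return np.vstack([self.highpass_sos, self.lowpass_sos, self.notch_sos])

    def frequency_response(self, freqs_hz) -> np.ndarray:
        """Complex response of the full chain at the given frequencies."""
        _, h = sps.sosfreqz(self.sos, worN=np.atleast_1d(freqs_hz),
                            fs=self.sample_rate_hz)
        return h

    def bandpass_response(self, freqs_hz) -> np.ndarray:
        """Response of the high-pass/low-pass pair only (no notch)."""
        pair = np.vstack([self.highpass_sos, self.lowpass_sos])
        _, h = sps.sosfreqz(pair, worN=np.atleast_1d(freqs_hz),
                            fs=self.sample_rate_hz)
        return h


def design_filter_chain(
    sample_rate_hz: float = 250.0,
    highpass_hz: float = 0.1,
    lowpass_hz: float = 9.0,
    notch_band_hz: tuple[float, float] = (48.0, 52.0),
    notch_ripple_db: float = 0.5,
) -> FilterChain:
    """Design the speller's filter chain at a given sample rate.

    The notch is a third-order Chebyshev type-I band-stop (realized as two
    cascaded third-order half-sections); ripple and bandwidth are free
    parameters of the design.
    """
    if sample_rate_hz <= 100.0:
        raise ValueError("sample_rate_hz must exceed 100 Hz (50 Hz notch below Nyquist)")
    nyq = sample_rate_hz / 2.0
    for f in (highpass_hz, lowpass_hz, *notch_band_hz):
        if not 0.0 < f < nyq:
            raise ValueError("all cutoffs must lie strictly inside (0, Nyquist)")
    hp = sps.butter(1, highpass_hz, btype="highpass", fs=sample_rate_hz, output="sos")
    lp = sps.butter(2, lowpass_hz, btype="lowpass", fs=sample_rate_hz, output="sos")
    notch = sps.cheby1(3, notch_ripple_db, notch_band_hz, btype="bandstop",
                       fs=sample_rate_hz, output="sos")
    return FilterChain(hp, lp, notch, sample_rate_hz)


def apply_filter_chain(chain: FilterChain, signal, zero_phase: bool = False) -> np.ndarray:
    """Filter a channels x samples array through the chain.

    Causal (forward-only) by default to mirror online operation;
    ``zero_phase=True`` applies forward-backward filtering instead.
    """
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input signal contains non-finite values")
    if zero_phase:
        return sps.sosfiltfilt(chain.sos, x, axis=-1)
    return sps.sosfilt(chain.sos, x, axis=-1)


def extract_epochs(signal, events: list[StimulusEvent],
                   timing: TimingConfig = TimingConfig()) -> EpochSet:
    """Cut one fixed-length window per stimulus event from a continuous signal.

    The window is ``timing.epoch_window_s`` relative to each onset (0-800 ms,
    i.e. 200 samples, at defaults).  Windows may overlap freely; an event
    whose window leaves the signal raises, naming the offending event.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 2:
        raise ValueError("signal must be channels x samples")
    n_samples = x.shape[1]
    offset = timing.epoch_offset_samples
    length = timing.epoch_samples
    if not events:
        return EpochSet(np.empty((0, x.shape[0], length)), [])
    windows = []
    for i, ev in enumerate(events):
        start = ev.onset_sample + offset
        stop = start + length
        if start < 0 or stop > n_samples:
            raise ValueError(
                f"epoch window [{start}, {stop}) of event {i} "
                f"(onset {ev.onset_sample}) exceeds signal bounds (0, {n_samples})"
            )
        windows.append(x[:, start:stop])
    return EpochSet(np.stack(windows), list(events))


def decimate_features(epochs: np.ndarray, factor: int) -> np.ndarray:
    """Optional temporal decimation of epochs before classification (off by
    default in the pipeline); keeps every ``factor``-th sample."""
    if factor < 1:
        raise ValueError("decimation factor must be >= 1")
    return epochs[..., ::factor]
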