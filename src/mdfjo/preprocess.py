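"""Spatial re-referencing, band-pass filtering and segmentation grids.

Processing order for the whole pipeline is fixed: epoching, common
average reference, broad 4-40 Hz band-pass, then per-view sub-band
filtering of the full epoch followed by time-window slicing. Sub-band
filters run on the full epoch (not the slice) so that 2 s windows do not
inherit filter edge artifacts.

All filtering is zero-phase: the Butterworth filter is applied forward
and backward (``sosfiltfilt``), which doubles the effective order but
introduces no group delay — important because time windows are compared
against cue-locked latencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import EpochedTrials

__all__ = [
    "BandGrid",
    "TimeGrid",
    "apply_car",
    "bandpass",
    "make_band_grid",
    "make_time_grid",
    "slice_window",
]


@dataclass(frozen=True)
class BandGrid:
    """Ordered overlapping frequency sub-bands, (low_hz, high_hz) pairs."""

    bands: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        for lo, hi in self.bands:
            if not lo < hi:
                raise ValueError(f"band ({lo}, {hi}) has low >= high")
        lows = [b[0] for b in self.bands]
        if lows != sorted(lows):
            raise ValueError("bands must be sorted by low edge")

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)


@dataclass(frozen=True)
class TimeGrid:
    """Ordered overlapping time windows, (start_s, end_s) pairs relative to cue onset."""

    windows: tuple[tuple[float, float], ...]

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)


def apply_car(trials: EpochedTrials) -> EpochedTrials:
    """Common average reference: subtract the instantaneous channel mean.

    After CAR the mean across channels is zero at every sample, removing
    common-mode components (reference drift, widespread artifacts).
    """
    if trials.n_channels < 2:
        raise ValueError("CAR requires at least 2 channels")
    out = trials.data - trials.data.mean(axis=1, keepdims=True)
    return trials.with_data(out)


def _butter_sos(low_hz: float, high_hz: float, fs: float, order: int):
    nyq = fs / 2.0
    if not 0 < low_hz < high_hz:
        raise ValueError(f"need 0 < low < high, got ({low_hz}, {high_hz})")
    if high_hz >= nyq:
        raise ValueError(f"high edge {high_hz} Hz >= Nyquist {nyq} Hz")
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def bandpass(
    trials: EpochedTrials, low_hz: float, high_hz: float, order: int = 5
) -> EpochedTrials:
    """Zero-phase Butterworth band-pass along the sample axis."""
    sos = _butter_sos(low_hz, high_hz, trials.fs, order)
    out = signal.sosfiltfilt(sos, trials.data, axis=-1)
    return trials.with_data(out)


def bandpass_array(x: np.ndarray, fs: float, low_hz: float, high_hz: float, order: int = 5) -> np.ndarray:
    """`bandpass` on a bare array (sample axis last)."""
    sos = _butter_sos(low_hz, high_hz, fs, order)
    return signal.sosfiltfilt(sos, x, axis=-1)


def make_band_grid(fmin: float, fmax: float, width: float, step: float) -> BandGrid:
    """Overlapping sub-band grid: bands of `width` Hz every `step` Hz from `fmin`.

    ``(4, 40, 4, 2)`` gives the canonical 17-band filter bank
    4-8, 6-10, ..., 36-40 Hz (4 Hz width, 50% overlap).
    """
    if not fmin < fmax:
        raise ValueError(f"need fmin < fmax, got ({fmin}, {fmax})")
    if not 0 < step <= width:
        raise ValueError(f"need 0 < step <= width, got step={step}, width={width}")
    if fmin + width > fmax:
        raise ValueError(f"width {width} does not fit in [{fmin}, {fmax}]")
    n = int(np.floor((fmax - width - fmin) / step + 1e-9)) + 1
    bands = tuple((fmin + i * step, fmin + i * step + width) for i in range(n))
    return BandGrid(bands)


def make_time_grid(duration_s: float, win_s: float, step_s: float) -> TimeGrid:
    """Sliding time-window grid: `win_s`-long windows every `step_s` seconds.

    ``(4.0, 2.0, 0.5)`` gives the five windows 0-2, 0.5-2.5, ..., 2-4 s;
    a 3.5 s epoch gives four.
    """
    if win_s > duration_s:
        raise ValueError(f"window {win_s}s longer than epoch {duration_s}s")
    if not step_s > 0:
        raise ValueError("step must be positive")
    n = int(np.floor((duration_s - win_s) / step_s + 1e-9)) + 1
    windows = tuple((i * step_s, i * step_s + win_s) for i in range(n))
    return TimeGrid(windows)


def window_slice(window: tuple[float, float], fs: float, n_samples: int) -> slice:
    """Half-open sample slice [round(start*fs), round(end*fs)) for a window."""
    start, end = window
    i0 = int(round(start * fs))
    i1 = int(round(end * fs))
    if i0 < 0 or i1 > n_samples or i0 >= i1:
        raise ValueError(f"window {window} outside epoch of {n_samples} samples")
    return slice(i0, i1)


def slice_window(trials: EpochedTrials, window: tuple[float, float]) -> EpochedTrials:
    """Extract the samples of one time window (half-open, 0-based)."""
    sl = window_slice(window, trials.fs, trials.n_samples)
    return trials.with_data(trials.data[:, :, sl])
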