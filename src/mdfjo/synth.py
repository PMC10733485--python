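"""Synthetic two-class motor-imagery-like EEG with known ground truth.

Each trial is the sum of three components:

* an independent 1/f background per channel (power spectral density
  proportional to ``1/f**exponent``), emulating broadband EEG noise;
* a common-mode 1/f signal shared by all channels of a trial, emulating
  reference drift removed by CAR;
* a band-limited oscillation (band-pass filtered white noise, not a pure
  sinusoid, so within-band variance behaves like a real rhythm) on the
  *active* channels.

Class 2 trials attenuate the oscillation amplitude inside the ERD window
by the ``attenuation`` factor, with 100 ms raised-cosine ramps at the
window edges, mimicking event-related desynchronization of the mu rhythm:
the classes differ only in band-limited log-variance at the active
channels inside a sub-interval of the epoch. The manifest records which
bands and windows of the analysis grids overlap the planted effect.

The generator emulates the second-order statistics CSP-type decoders
consume; it does not model volume conduction, eye/muscle artifacts, or
trial-to-trial nonstationarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io import EpochedTrials
from .preprocess import BandGrid, TimeGrid, bandpass_array, make_band_grid, make_time_grid

__all__ = ["SyntheticSpec", "TruthManifest", "generate", "checkerboard_case", "TEN_TWENTY_NAMES"]

# Ordered so that the default active channels (3, 7) are the motor pair C3/C4.
TEN_TWENTY_NAMES = (
    "F5", "F3", "F1", "C3", "C1", "Cz", "C2", "C4",
    "F2", "F4", "F6", "FC3", "FC1", "FCz", "FC2", "FC4",
    "CP3", "CP1", "CPz", "CP2", "CP4", "P5", "P3", "P1",
    "Pz", "P2", "P4", "P6", "O1", "O2",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic two-class ERD dataset.

    Amplitudes are standard deviations in arbitrary microvolt-like units;
    ``attenuation`` multiplies the class-2 oscillation amplitude inside
    ``erd_window`` (power ratio class1/class2 of the planted rhythm is
    therefore 1/attenuation**2).
    """

    n_per_class: int = 100
    n_channels: int = 20
    fs: float = 100.0
    duration_s: float = 4.0
    active_channels: tuple[int, ...] = (3, 7)
    erd_band: tuple[float, float] = (10.0, 14.0)
    erd_window: tuple[float, float] = (0.5, 2.5)
    attenuation: float = 0.5
    background_exponent: float = 1.0
    background_amp: float = 1.0
    common_mode_amp: float = 0.5
    osc_amp: float = 2.0
    ramp_s: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.attenuation <= 1:
            raise ValueError("attenuation must be in (0, 1]")
        if any(not 0 <= c < self.n_channels for c in self.active_channels):
            raise ValueError("active_channels out of range")
        if not (0 <= self.erd_window[0] < self.erd_window[1] <= self.duration_s):
            raise ValueError("erd_window must lie inside the epoch")
        if not (0 < self.erd_band[0] < self.erd_band[1] < self.fs / 2):
            raise ValueError("erd_band must lie below Nyquist")


@dataclass(frozen=True)
class TruthManifest:
    """Ground truth of a generated dataset, expressed against analysis grids."""

    spec: SyntheticSpec
    erd_band_indices: tuple[int, ...]
    erd_window_indices: tuple[int, ...]

    def to_dict(self) -> dict:
        return {
            "spec": asdict(self.spec),
            "erd_band_indices": list(self.erd_band_indices),
            "erd_window_indices": list(self.erd_window_indices),
        }


def _overlapping(intervals, target) -> tuple[int, ...]:
    lo, hi = target
    return tuple(
        i for i, (a, b) in enumerate(intervals) if min(b, hi) - max(a, lo) > 0
    )


def default_manifest_grids(spec: SyntheticSpec) -> tuple[BandGrid, TimeGrid]:
    return (
        make_band_grid(4.0, 40.0, 4.0, 2.0),
        make_time_grid(spec.duration_s, 2.0, 0.5),
    )


def one_over_f_noise(
    rng: np.random.Generator, shape: tuple[int, ...], n_samples: int, fs: float, exponent: float
) -> np.ndarray:
    """Unit-RMS noise with power spectral density proportional to 1/f^exponent."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (
        rng.standard_normal(shape + (len(freqs),))
        + 1j * rng.standard_normal(shape + (len(freqs),))
    ) * amp
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _erd_envelope(spec: SyntheticSpec, n_samples: int) -> np.ndarray:
    """Class-2 amplitude envelope: `attenuation` inside the ERD window,
    1 outside, raised-cosine ramps of `ramp_s` at the edges."""
    t = np.arange(n_samples) / spec.fs
    t0, t1 = spec.erd_window
    ramp = min(spec.ramp_s, (t1 - t0) / 2)
    env = np.ones(n_samples)
    att = spec.attenuation
    inside = (t >= t0) & (t < t1)
    env[inside] = att
    if ramp > 0:
        down = (t >= t0) & (t < t0 + ramp)
        env[down] = 1 + (att - 1) * 0.5 * (1 - np.cos(np.pi * (t[down] - t0) / ramp))
        up = (t >= t1 - ramp) & (t < t1)
        env[up] = att + (1 - att) * 0.5 * (1 - np.cos(np.pi * (t[up] - (t1 - ramp)) / ramp))
    return env


def _channel_names(n: int) -> tuple[str, ...]:
    names = list(TEN_TWENTY_NAMES[:n])
    names += [f"EXT{i}" for i in range(len(names), n)]
    return tuple(names)


def generate(spec: SyntheticSpec) -> tuple[EpochedTrials, TruthManifest]:
    """Generate a balanced two-class dataset per `spec`, deterministically."""
    rng = np.random.default_rng(spec.seed)
    n_trials = 2 * spec.n_per_class
    n_samples = int(round(spec.duration_s * spec.fs))
    labels = np.repeat([1, 2], spec.n_per_class)

    data = spec.background_amp * one_over_f_noise(
        rng, (n_trials, spec.n_channels), n_samples, spec.fs, spec.background_exponent
    )
    common = spec.common_mode_amp * one_over_f_noise(
        rng, (n_trials,), n_samples, spec.fs, spec.background_exponent
    )
    data += common[:, None, :]

    # band-limited rhythm on the active channels, attenuated in-window for class 2
    raw = rng.standard_normal((n_trials, len(spec.active_channels), n_samples))
    osc = bandpass_array(raw, spec.fs, spec.erd_band[0], spec.erd_band[1], order=4)
    osc = spec.osc_amp * osc / osc.std(axis=-1, keepdims=True)
    env = _erd_envelope(spec, n_samples)
    osc[labels == 2] *= env
    for j, ch in enumerate(spec.active_channels):
        data[:, ch, :] += osc[:, j, :]

    trials = EpochedTrials(
        data=data,
        labels=labels,
        fs=spec.fs,
        channel_names=_channel_names(spec.n_channels),
        epoch_start=0.0,
    )
    band_grid, time_grid = default_manifest_grids(spec)
    manifest = TruthManifest(
        spec=spec,
        erd_band_indices=_overlapping(band_grid, spec.erd_band),
        erd_window_indices=_overlapping(time_grid, spec.erd_window),
    )
    return trials, manifest


def checkerboard_case() -> tuple[EpochedTrials, TruthManifest]:
    """Tiny fixed fixture: 20 trials, 6 channels, 2 s, one planted channel.

    The oscillation sits on channel 2 in 10-14 Hz and is attenuated for the
    whole epoch in class 2, so the best channel, band and window are known
    by construction. No common-mode component: the planted channel is then
    provably the dominant direction of the class contrast. Fixed seed;
    byte-identical across calls.
    """
    spec = SyntheticSpec(
        n_per_class=10,
        n_channels=6,
        fs=100.0,
        duration_s=2.0,
        active_channels=(2,),
        erd_band=(10.0, 14.0),
        erd_window=(0.0, 2.0),
        attenuation=0.3,
        background_amp=1.0,
        common_mode_amp=0.0,
        osc_amp=1.5,
        seed=1234,
    )
    return generate(spec)
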