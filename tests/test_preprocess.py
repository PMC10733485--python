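import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mdfjo.io import EpochedTrials
from mdfjo.preprocess import (
    apply_car,
    bandpass,
    make_band_grid,
    make_time_grid,
    slice_window,
)
from tests.conftest import random_trials


def _sine_trials(freq, fs=100.0, n_samples=400, n_channels=3):
    t = np.arange(n_samples) / fs
    data = np.tile(np.sin(2 * np.pi * freq * t), (1, n_channels, 1))
    return EpochedTrials(
        data=data, labels=np.array([1]), fs=fs, channel_names=("a", "b", "c")
    )


class TestCAR:
    def test_channel_means_are_zero_per_sample(self, rng):
        out = apply_car(random_trials(rng))
        assert np.abs(out.data.mean(axis=1)).max() < 1e-10

    def test_common_offset_removed_entirely(self):
        data = np.full((2, 4, 50), 3.7)
        trials = EpochedTrials(
            data=data, labels=np.array([1, 2]), fs=100.0, channel_names=tuple("abcd")
        )
        assert np.abs(apply_car(trials).data).max() == 0

    def test_common_mode_removed_unique_parts_kept(self, rng):
        # planted common sinusoid + channel-unique signals; CAR must subtract
        # exactly the common mode plus the mean of the unique parts
        fs, n = 100.0, 400
        t = np.arange(n) / fs
        common = np.sin(2 * np.pi * 7 * t)
        unique = rng.standard_normal((1, 4, n))
        data = unique + common
        trials = EpochedTrials(
            data=data, labels=np.array([1]), fs=fs, channel_names=tuple("abcd")
        )
        expected = unique - unique.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(apply_car(trials).data, expected, atol=1e-8)

    def test_idempotent(self, rng):
        once = apply_car(random_trials(rng))
        twice = apply_car(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-10)

    def test_single_channel_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_car(random_trials(rng, n_channels=1))


class TestBandpass:
    def test_passband_tone_preserved(self):
        trials = _sine_trials(20.0)
        out = bandpass(trials, 4, 40, order=5)
        ratio = np.sqrt((out.data**2).mean() / (trials.data**2).mean())
        assert 0.95 < ratio < 1.05

    def test_stopband_tone_suppressed(self):
        trials = _sine_trials(1.0)
        out = bandpass(trials, 4, 40, order=5)
        ratio = np.sqrt((out.data**2).mean() / (trials.data**2).mean())
        assert ratio < 0.1

    def test_zero_signal_maps_to_zero(self):
        trials = _sine_trials(20.0).with_data(np.zeros((1, 3, 400)))
        assert np.abs(bandpass(trials, 4, 40).data).max() == 0

    def test_high_edge_above_nyquist_rejected(self, rng):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(random_trials(rng), 4, 60)


class TestGrids:
    def test_canonical_17_band_grid(self):
        grid = make_band_grid(4, 40, 4, 2)
        assert len(grid) == 17
        assert grid.bands[0] == (4, 8)
        assert grid.bands[-1] == (36, 40)

    @pytest.mark.parametrize(
        "args, expected",
        [
            ((4, 8, 4, 2), ((4, 8),)),
            ((4, 12, 4, 4), ((4, 8), (8, 12))),
        ],
    )
    def test_small_band_grids(self, args, expected):
        assert make_band_grid(*args).bands == expected

    @pytest.mark.parametrize(
        "args, n, first, last",
        [
            ((4.0, 2.0, 0.5), 5, (0.0, 2.0), (2.0, 4.0)),
            ((3.5, 2.0, 0.5), 4, (0.0, 2.0), (1.5, 3.5)),
            ((2.0, 2.0, 0.5), 1, (0.0, 2.0), (0.0, 2.0)),
        ],
    )
    def test_time_grids(self, args, n, first, last):
        grid = make_time_grid(*args)
        assert len(grid) == n
        assert grid.windows[0] == first
        assert grid.windows[-1] == last

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ValueError):
            make_band_grid(40, 4, 4, 2)
        with pytest.raises(ValueError):
            make_time_grid(1.0, 2.0, 0.5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        fmin=st.integers(1, 10),
        span=st.integers(1, 40),
        width=st.integers(1, 12),
        step=st.integers(1, 12),
    )
    def test_band_count_matches_brute_force(self, fmin, span, width, step):
        fmax = fmin + span
        if step > width or fmin + width > fmax:
            return
        grid = make_band_grid(fmin, fmax, width, step)
        # brute force: enumerate starts until the band no longer fits
        expected = [s for s in range(fmin, fmax + 1) if (s - fmin) % step == 0 and s + width <= fmax]
        assert len(grid) == len(expected)
        assert [b[0] for b in grid] == expected

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(dur=st.integers(2, 40), win=st.integers(1, 10), step=st.integers(1, 6))
    def test_window_count_matches_brute_force(self, dur, win, step):
        if win > dur:
            return
        grid = make_time_grid(float(dur), float(win), float(step))
        expected = [s for s in range(0, dur + 1) if s % step == 0 and s + win <= dur]
        assert len(grid) == len(expected)


class TestSliceWindow:
    def test_sample_counts(self, rng):
        trials = random_trials(rng, n_samples=400)
        assert slice_window(trials, (0.0, 2.0)).n_samples == 200

    def test_half_open_indexing(self, rng):
        trials = random_trials(rng, n_samples=400)
        out = slice_window(trials, (1.5, 3.5))
        np.testing.assert_array_equal(out.data, trials.data[:, :, 150:350])

    def test_reslice_identity(self, rng):
        trials = random_trials(rng, n_samples=200)
        once = slice_window(trials, (0.0, 2.0))
        np.testing.assert_array_equal(slice_window(once, (0.0, 2.0)).data, once.data)

    def test_out_of_epoch_window_rejected(self, rng):
        with pytest.raises(ValueError):
            slice_window(random_trials(rng, n_samples=100), (0.0, 2.0))
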