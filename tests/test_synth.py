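import numpy as np
import pytest

from mdfjo.preprocess import apply_car, bandpass_array
from mdfjo.synth import (
    SyntheticSpec,
    checkerboard_case,
    generate,
    one_over_f_noise,
)


def band_power(trials, spec, window, channels):
    """Mean in-band variance of `channels` inside a time window, per class."""
    filt = bandpass_array(trials.data, spec.fs, *spec.erd_band, order=4)
    i0, i1 = int(window[0] * spec.fs), int(window[1] * spec.fs)
    seg = filt[:, :, i0:i1][:, channels, :]
    var = seg.var(axis=-1).mean(axis=1)
    return var[trials.labels == 1].mean(), var[trials.labels == 2].mean()


class TestGenerate:
    def test_shapes_balance_and_determinism(self):
        spec = SyntheticSpec(n_per_class=20, n_channels=8, seed=5)
        t1, m1 = generate(spec)
        t2, _ = generate(spec)
        assert t1.data.shape == (40, 8, 400)
        assert (t1.labels == 1).sum() == (t1.labels == 2).sum() == 20
        np.testing.assert_array_equal(t1.data, t2.data)

    def test_active_channel_power_ratio_matches_attenuation(self):
        # class1/class2 in-band power ratio ~ 1/attenuation^2, measured on
        # the flat interior of the ERD window (inside the cosine ramps)
        ratios = []
        for seed in range(20):
            spec = SyntheticSpec(n_per_class=30, seed=seed)
            trials, _ = generate(spec)
            flat = (spec.erd_window[0] + spec.ramp_s, spec.erd_window[1] - spec.ramp_s)
            p1, p2 = band_power(trials, spec, flat, list(spec.active_channels))
            ratios.append(p1 / p2)
        target = 1.0 / SyntheticSpec().attenuation**2
        assert abs(np.mean(ratios) - target) / target < 0.10

    def test_inactive_channels_have_no_class_difference(self):
        ratios = []
        for seed in range(5):
            spec = SyntheticSpec(n_per_class=50, seed=seed)
            trials, _ = generate(spec)
            inactive = [c for c in range(spec.n_channels) if c not in spec.active_channels]
            p1, p2 = band_power(trials, spec, spec.erd_window, inactive)
            ratios.append(p1 / p2)
        assert abs(np.mean(ratios) - 1.0) < 0.05

    def test_no_class_difference_outside_erd_window(self):
        ratios = []
        for seed in range(5):
            spec = SyntheticSpec(n_per_class=50, seed=seed)
            trials, _ = generate(spec)
            p1, p2 = band_power(trials, spec, (3.0, 4.0), list(spec.active_channels))
            ratios.append(p1 / p2)
        assert abs(np.mean(ratios) - 1.0) < 0.05

    def test_attenuation_one_removes_class_structure(self):
        spec = SyntheticSpec(n_per_class=50, attenuation=1.0, seed=3)
        trials, _ = generate(spec)
        p1, p2 = band_power(trials, spec, spec.erd_window, list(spec.active_channels))
        assert abs(p1 / p2 - 1.0) < 0.05

    def test_manifest_indices_match_planted_effect(self):
        _, manifest = generate(SyntheticSpec(seed=0))
        # 10-14 Hz overlaps the 8-12, 10-14, 12-16 bands of the 17-band grid
        assert manifest.erd_band_indices == (2, 3, 4)
        # 0.5-2.5 s overlaps every 2 s window of a 4 s epoch
        assert manifest.erd_window_indices == (0, 1, 2, 3, 4)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(attenuation=0.0)
        with pytest.raises(ValueError):
            SyntheticSpec(active_channels=(99,))
        with pytest.raises(ValueError):
            SyntheticSpec(erd_window=(3.0, 5.0))


class TestBackground:
    def test_spectral_slope_matches_exponent(self):
        # periodogram log-log slope of the 1/f background ~ -exponent
        rng = np.random.default_rng(0)
        slopes = []
        for _ in range(20):
            x = one_over_f_noise(rng, (8,), 1024, 100.0, exponent=1.0)
            f = np.fft.rfftfreq(1024, 0.01)
            p = (np.abs(np.fft.rfft(x, axis=-1)) ** 2).mean(axis=0)
            sel = (f >= 1) & (f <= 40)
            slopes.append(np.polyfit(np.log(f[sel]), np.log(p[sel]), 1)[0])
        assert abs(np.mean(slopes) + 1.0) < 0.3

    def test_car_removes_common_mode_exactly(self):
        spec0 = SyntheticSpec(n_per_class=10, common_mode_amp=0.0, seed=11)
        spec1 = SyntheticSpec(n_per_class=10, common_mode_amp=0.8, seed=11)
        t0, _ = generate(spec0)
        t1, _ = generate(spec1)
        # same seed: the datasets differ only by the common-mode component,
        # which CAR must subtract entirely
        np.testing.assert_allclose(
            apply_car(t1).data, apply_car(t0).data, atol=1e-10
        )
        residual = np.sqrt(((apply_car(t1).data - apply_car(t0).data) ** 2).mean())
        assert residual <= 0.01 * np.sqrt((t1.data**2).mean())


class TestCheckerboard:
    def test_fixture_is_reproducible(self):
        t1, m1 = checkerboard_case()
        t2, m2 = checkerboard_case()
        np.testing.assert_array_equal(t1.data, t2.data)
        assert m1.spec == m2.spec

    def test_fixture_dimensions(self, checkerboard):
        trials, manifest = checkerboard
        assert trials.data.shape == (20, 6, 200)
        assert manifest.spec.active_channels == (2,)
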