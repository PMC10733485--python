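import numpy as np
import pytest

from mdfjo.channels import rank_channels
from mdfjo.csp import (
    build_views,
    csp_eigenvalues,
    csp_fit,
    csp_logvar,
    transform_views,
    trial_covariances,
)
from mdfjo.preprocess import make_band_grid, make_time_grid
from tests.conftest import random_trials


def _two_class_toy(rng, n=30, T=500):
    """Class 1 has variance only on channel 1, class 2 only on channel 2."""
    x1 = np.zeros((n, 2, T))
    x2 = np.zeros((n, 2, T))
    x1[:, 0] = rng.standard_normal((n, T))
    x1[:, 1] = 0.01 * rng.standard_normal((n, T))
    x2[:, 1] = rng.standard_normal((n, T))
    x2[:, 0] = 0.01 * rng.standard_normal((n, T))
    return x1, x2


class TestCSPFit:
    def test_equal_covariance_gives_half_eigenvalues(self, rng):
        x = rng.standard_normal((40, 4, 300))
        vals = csp_eigenvalues(x, x, shrinkage=0.0)
        np.testing.assert_allclose(vals, 0.5, atol=1e-8)

    def test_axis_aligned_toy_recovers_unit_filters(self, rng):
        x1, x2 = _two_class_toy(rng)
        W = csp_fit(x1, x2, m=1, shrinkage=0.0)
        # top filter concentrates on channel 1's axis, bottom on channel 2's
        assert abs(W[0, 0]) / np.linalg.norm(W[:, 0]) > 0.99
        assert abs(W[1, 1]) / np.linalg.norm(W[:, 1]) > 0.99

    def test_class_swap_reverses_filter_order(self, rng):
        x1, x2 = _two_class_toy(rng)
        W12 = csp_fit(x1, x2, m=1, shrinkage=0.05)
        W21 = csp_fit(x2, x1, m=1, shrinkage=0.05)
        np.testing.assert_allclose(np.abs(W21), np.abs(W12[:, ::-1]), atol=1e-8)

    def test_eigenvalue_swap_symmetry(self, rng):
        x1 = rng.standard_normal((30, 3, 200))
        x2 = 1.5 * rng.standard_normal((30, 3, 200))
        v12 = csp_eigenvalues(x1, x2)
        v21 = csp_eigenvalues(x2, x1)
        np.testing.assert_allclose(np.sort(v12), np.sort(1 - v21), atol=1e-10)

    def test_eigenvalues_in_unit_interval_extremes_straddle_half(self, rng):
        x1 = rng.standard_normal((20, 5, 200))
        x2 = rng.standard_normal((20, 5, 200)) * rng.uniform(0.5, 2, size=(1, 5, 1))
        vals = csp_eigenvalues(x1, x2)
        assert np.all(vals >= -1e-12) and np.all(vals <= 1 + 1e-12)
        assert vals[-1] >= 0.5 - 1e-12 >= vals[0] - 1e-10

    def test_singular_covariance_without_shrinkage_raises(self, rng):
        # 4 channels but rank-1 trials -> singular composite covariance
        base = rng.standard_normal((10, 1, 50))
        x = np.repeat(base, 4, axis=1)
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            csp_fit(x, x + 0.0, m=1, shrinkage=0.0)

    def test_too_few_trials_rejected(self, rng):
        x = rng.standard_normal((1, 2, 50))
        with pytest.raises(ValueError):
            csp_fit(x, x, m=1)


class TestLogvar:
    def test_unit_variance_projection_gives_zero(self):
        T = 1000
        x = np.sign(np.sin(np.arange(T) * 1.7)) * 1.0
        x = x - x.mean()
        x = (x / x.std())[None, :]
        f = csp_logvar(np.eye(1), x)
        np.testing.assert_allclose(f, 0.0, atol=1e-10)

    def test_trial_scaling_shifts_features_by_2logc(self, rng):
        W = rng.standard_normal((3, 2))
        trial = rng.standard_normal((3, 100))
        f1 = csp_logvar(W, trial)
        f2 = csp_logvar(W, 3.0 * trial)
        np.testing.assert_allclose(f2 - f1, 2 * np.log(3.0), atol=1e-10)

    def test_hand_computed_two_channel_trial(self):
        W = np.array([[1.0, 0.5], [-1.0, 2.0]])
        trial = np.array([[1.0, 2.0, 3.0, 4.0], [0.0, 1.0, -1.0, 2.0]])
        Z = W.T @ trial
        expected = np.log(((Z - Z.mean(axis=1, keepdims=True)) ** 2).mean(axis=1))
        np.testing.assert_allclose(csp_logvar(W, trial), expected, atol=1e-10)

    def test_channel_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="channels"):
            csp_logvar(np.eye(3), rng.standard_normal((2, 50)))

    def test_quadratic_form_equals_direct_computation(self, rng):
        # the covariance fast path must match projecting the raw signal
        data = rng.standard_normal((5, 4, 100))
        W = rng.standard_normal((4, 2))
        covs = trial_covariances(data)
        direct = np.array([csp_logvar(W, tr) for tr in data])
        quad = np.log(np.einsum("cp,ncd,dp->np", W, covs, W))
        np.testing.assert_allclose(quad, direct, atol=1e-10)


class TestViews:
    def test_view_and_column_counts(self, rng):
        trials = random_trials(rng, n_trials=40, n_channels=6, n_samples=400)
        ranking = rank_channels(trials)
        bank, views = build_views(
            trials, ranking, make_band_grid(4, 40, 4, 2),
            make_time_grid(4.0, 2.0, 0.5), mode_sizes=(2, 4, 6),
        )
        assert len(views) == 15  # 3 modes x 5 windows
        assert all(v.X.shape == (40, 34) for v in views)  # 2mk = 2*1*17

    def test_transform_reproduces_training_features(self, rng):
        trials = random_trials(rng, n_trials=20, n_channels=4, n_samples=300)
        ranking = rank_channels(trials)
        bank, views = build_views(
            trials, ranking, make_band_grid(8, 16, 4, 4),
            make_time_grid(3.0, 2.0, 1.0), mode_sizes=(4,),
        )
        again = transform_views(trials, bank)
        for v1, v2 in zip(views, again):
            np.testing.assert_array_equal(v1.X, v2.X)

    def test_channel_permutation_invariance(self, rng):
        trials = random_trials(rng, n_trials=30, n_channels=5, n_samples=300)
        perm = np.array([4, 2, 0, 3, 1])
        permuted = trials.with_data(trials.data[:, perm, :])
        grid_b, grid_t = make_band_grid(8, 16, 4, 4), make_time_grid(3.0, 2.0, 1.0)
        r1, r2 = rank_channels(trials), rank_channels(permuted)
        _, v1 = build_views(trials, r1, grid_b, grid_t, (5,))
        _, v2 = build_views(permuted, r2, grid_b, grid_t, (5,))
        for a, b in zip(v1, v2):
            np.testing.assert_allclose(a.X, b.X, atol=1e-8)

    def test_top_filter_beats_every_single_channel(self, checkerboard):
        # variance-ratio contrast of the top CSP filter must exceed that of
        # any raw channel (exhaustive single-channel oracle)
        trials, _ = checkerboard
        from mdfjo.preprocess import bandpass

        band = bandpass(trials, 4, 40)
        x1 = band.data[band.labels == 1]
        x2 = band.data[band.labels == 2]
        W = csp_fit(x1, x2, m=1, shrinkage=0.05)
        w = W[:, 0]

        def contrast(v1, v2):
            return max(v1 / v2, v2 / v1)

        proj1 = np.einsum("c,ncs->ns", w, x1).var(axis=1).mean()
        proj2 = np.einsum("c,ncs->ns", w, x2).var(axis=1).mean()
        csp_contrast = contrast(proj1, proj2)
        chan_contrast = max(
            contrast(x1[:, c].var(axis=1).mean(), x2[:, c].var(axis=1).mean())
            for c in range(trials.n_channels)
        )
        assert csp_contrast >= chan_contrast

    def test_checkerboard_top_filter_concentrates_on_planted_channel(self, checkerboard):
        trials, manifest = checkerboard
        from mdfjo.preprocess import bandpass

        band = bandpass(trials, 4, 40)
        W = csp_fit(band.data[band.labels == 1], band.data[band.labels == 2])
        w = np.abs(W[:, 0])
        assert w[manifest.spec.active_channels[0]] / w.sum() >= 0.8
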