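"""Common spatial patterns per (channel mode, time window, sub-band) view.

CSP solves the generalized eigenproblem of the two class-mean covariance
matrices, ``C1 w = lambda (C1 + C2) w``; the eigenvectors with the m
largest and m smallest eigenvalues maximize the variance ratio between
classes in the projected signal Z = W^T X. The per-trial feature is the
log-variance of each projected row, ``f_p = log(var(Z_p))``.

Per-trial covariances are trace-normalized before averaging (removes
inter-trial amplitude nuisance) and the class means are shrunk toward a
scaled identity to condition the eigenproblem when windows are short
relative to the channel count.

One view is one (channel mode s, time window t) pair; its feature matrix
stacks the 2m CSP features of all k sub-bands, band-major, giving
``N x 2mk`` per view. Because the log-variance of a projection is a
quadratic form in the trial covariance, the whole bank is fitted and
applied from per-trial covariance tensors computed once per dataset —
algebraically identical to filtering and projecting raw signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .channels import ChannelRanking, build_modes
from .io import EpochedTrials
from .preprocess import BandGrid, TimeGrid, bandpass_array, window_slice

__all__ = [
    "CSPFilterBank",
    "ViewFeatures",
    "csp_fit",
    "csp_eigenvalues",
    "csp_logvar",
    "trial_covariances",
    "compute_cov_tensors",
    "build_views",
    "transform_views",
]


@dataclass(frozen=True)
class ViewFeatures:
    """CSP log-variance feature matrix of one (mode, window) view.

    ``X`` is ``(n_trials, 2*m*k)``, columns ordered band-major then filter
    index; ``y`` is the shared +/-1 label vector; ``index[j] = (band, filter)``
    identifies column j.
    """

    X: np.ndarray
    y: np.ndarray
    index: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("feature matrix and labels disagree on trial count")
        if self.X.shape[1] != len(self.index):
            raise ValueError("column index does not cover the feature matrix")


@dataclass
class CSPFilterBank:
    """Fitted spatial filters for every (mode s, window t, band b) triple.

    ``filters[(s, t, b)]`` is the ``channels_in_mode x 2m`` filter matrix;
    ``modes[s]`` the channel indices of mode s; ``class_order`` the label
    mapped to +1 (first) and -1 (second).
    """

    filters: dict[tuple[int, int, int], np.ndarray]
    modes: list[np.ndarray]
    band_grid: BandGrid
    time_grid: TimeGrid
    m: int
    shrinkage: float
    class_order: tuple[int, int]
    filter_order: int = 5

    @property
    def n_views(self) -> int:
        return len(self.modes) * len(self.time_grid)

    def view_ids(self) -> list[tuple[int, int]]:
        """(mode, window) pairs in window-major-within-mode order."""
        return [(s, t) for s in range(len(self.modes)) for t in range(len(self.time_grid))]

    def encode_labels(self, labels: np.ndarray) -> np.ndarray:
        y = np.where(np.asarray(labels) == self.class_order[0], 1.0, -1.0)
        return y


def trial_covariances(data: np.ndarray) -> np.ndarray:
    """Biased (1/T), mean-removed covariance of each trial.

    `data` is ``(trials, channels, samples)``; returns ``(trials, C, C)``.
    """
    centered = data - data.mean(axis=-1, keepdims=True)
    return centered @ centered.transpose(0, 2, 1) / data.shape[-1]


def _class_mean_cov(covs: np.ndarray, shrinkage: float) -> np.ndarray:
    traces = np.trace(covs, axis1=-2, axis2=-1)
    mean = (covs / traces[:, None, None]).mean(axis=0)
    if shrinkage > 0:
        M = mean.shape[0]
        mean = (1 - shrinkage) * mean + shrinkage * (np.trace(mean) / M) * np.eye(M)
    return mean


def _sign_fix(W: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(W), axis=0)
    signs = np.sign(W[idx, np.arange(W.shape[1])])
    signs[signs == 0] = 1.0
    return W * signs


def _fit_from_mean_covs(C1: np.ndarray, C2: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    try:
        vals, vecs = scipy.linalg.eigh(C1, C1 + C2)
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as exc:
        raise np.linalg.LinAlgError(
            "composite covariance is singular; use shrinkage > 0"
        ) from exc
    # ascending eigenvalues -> m largest first, then m smallest
    cols = list(range(len(vals) - 1, len(vals) - 1 - m, -1)) + list(range(m))
    W = _sign_fix(vecs[:, cols])
    return W, vals[cols]


def csp_fit(
    trials_class1: np.ndarray,
    trials_class2: np.ndarray,
    m: int = 1,
    shrinkage: float = 0.05,
) -> np.ndarray:
    """Fit CSP filters from raw per-class trial arrays.

    Returns ``W`` of shape ``(channels, 2m)``: columns are generalized
    eigenvectors of (C1, C1+C2), the m largest-eigenvalue ones first,
    each sign-fixed so its largest-magnitude entry is positive.
    """
    if len(trials_class1) < 2 or len(trials_class2) < 2:
        raise ValueError("CSP needs >= 2 trials per class")
    C1 = _class_mean_cov(trial_covariances(np.asarray(trials_class1)), shrinkage)
    C2 = _class_mean_cov(trial_covariances(np.asarray(trials_class2)), shrinkage)
    W, _ = _fit_from_mean_covs(C1, C2, m)
    return W


def csp_eigenvalues(
    trials_class1: np.ndarray,
    trials_class2: np.ndarray,
    shrinkage: float = 0.05,
) -> np.ndarray:
    """All generalized eigenvalues of (C1, C1+C2), ascending; each in [0, 1]."""
    C1 = _class_mean_cov(trial_covariances(np.asarray(trials_class1)), shrinkage)
    C2 = _class_mean_cov(trial_covariances(np.asarray(trials_class2)), shrinkage)
    vals = scipy.linalg.eigh(C1, C1 + C2, eigvals_only=True)
    return vals


def csp_logvar(W: np.ndarray, trial: np.ndarray) -> np.ndarray:
    """Log-variance features of one trial: ``f_p = log(var((W^T X)_p))``.

    Variance is the biased (1/T) estimator after mean removal.
    """
    if trial.shape[0] != W.shape[0]:
        raise ValueError(f"trial has {trial.shape[0]} channels, W expects {W.shape[0]}")
    Z = W.T @ trial
    Z = Z - Z.mean(axis=-1, keepdims=True)
    var = (Z**2).mean(axis=-1)
    if np.any(var <= 0):
        raise ValueError("zero-variance projection")
    return np.log(var)


def _logvar_from_covs(W: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Quadratic-form equivalent of :func:`csp_logvar` for a trial-cov stack."""
    var = ((covs @ W) * W[None]).sum(axis=1)
    if np.any(var <= 0):
        raise ValueError("zero-variance projection")
    return np.log(var)


def compute_cov_tensors(
    trials: EpochedTrials,
    band_grid: BandGrid,
    time_grid: TimeGrid,
    filter_order: int = 5,
) -> np.ndarray:
    """Per-trial covariance for every (band, window) pair.

    Each sub-band filter is applied to the full epoch, the filtered signal
    sliced per window, and the biased per-trial covariance taken. Returns
    ``(n_bands, n_windows, n_trials, C, C)``.
    """
    B, T = len(band_grid), len(time_grid)
    N, C = trials.n_trials, trials.n_channels
    out = np.empty((B, T, N, C, C))
    slices = [window_slice(w, trials.fs, trials.n_samples) for w in time_grid]
    for b, (lo, hi) in enumerate(band_grid):
        filt = bandpass_array(trials.data, trials.fs, lo, hi, filter_order)
        for t, sl in enumerate(slices):
            out[b, t] = trial_covariances(filt[:, :, sl])
    return out


def _fit_bank_from_covs(
    covs: np.ndarray,
    labels: np.ndarray,
    modes: list[np.ndarray],
    band_grid: BandGrid,
    time_grid: TimeGrid,
    m: int,
    shrinkage: float,
    class_order: tuple[int, int],
    filter_order: int,
) -> CSPFilterBank:
    labels = np.asarray(labels)
    mask1 = labels == class_order[0]
    mask2 = labels == class_order[1]
    diag = np.diagonal(covs, axis1=-2, axis2=-1)  # (B, T, N, C) view
    filters: dict[tuple[int, int, int], np.ndarray] = {}
    for s, mode in enumerate(modes):
        M = len(mode)
        eye = np.eye(M)
        # mean of trace-normalized mode submatrices == submatrix of the
        # 1/trace-weighted full-matrix mean (trace taken on the submatrix)
        tr = diag[..., mode].sum(axis=-1)  # (B, T, N)
        means = []
        for mask in (mask1, mask2):
            wts = np.where(mask, 1.0 / tr, 0.0) / mask.sum()
            full = np.einsum("btncd,btn->btcd", covs, wts, optimize=True)
            mean = full[:, :, mode[:, None], mode[None, :]]
            if shrinkage > 0:
                t_m = np.trace(mean, axis1=-2, axis2=-1) / M
                mean = (1 - shrinkage) * mean + shrinkage * t_m[..., None, None] * eye
            means.append(mean)
        for b in range(len(band_grid)):
            for t in range(len(time_grid)):
                W, _ = _fit_from_mean_covs(means[0][b, t], means[1][b, t], m)
                filters[(s, t, b)] = W
    return CSPFilterBank(
        filters=filters,
        modes=[np.asarray(mo) for mo in modes],
        band_grid=band_grid,
        time_grid=time_grid,
        m=m,
        shrinkage=shrinkage,
        class_order=class_order,
        filter_order=filter_order,
    )


def _views_from_covs(covs: np.ndarray, labels: np.ndarray, bank: CSPFilterBank) -> list[ViewFeatures]:
    y = bank.encode_labels(labels)
    k = len(bank.band_grid)
    n_ch = covs.shape[-1]
    views = []
    for s, mode in enumerate(bank.modes):
        for t in range(len(bank.time_grid)):
            cols, index = [], []
            for b in range(k):
                W = bank.filters[(s, t, b)]
                # embed the mode filters in full channel space: the quadratic
                # form then uses the full covariance without a submatrix copy
                Wf = np.zeros((n_ch, W.shape[1]))
                Wf[mode] = W
                cols.append(_logvar_from_covs(Wf, covs[b, t]))
                index.extend((b, p) for p in range(2 * bank.m))
            views.append(ViewFeatures(X=np.hstack(cols), y=y, index=tuple(index)))
    return views


def build_views(
    trials: EpochedTrials,
    ranking: ChannelRanking,
    band_grid: BandGrid,
    time_grid: TimeGrid,
    mode_sizes: tuple[int, ...],
    m: int = 1,
    shrinkage: float = 0.05,
    filter_order: int = 5,
    cov_tensors: np.ndarray | None = None,
) -> tuple[CSPFilterBank, list[ViewFeatures]]:
    """Fit the full filter bank and assemble per-view feature matrices.

    Views are ordered mode-major ((s=0,t=0), (s=0,t=1), ...); fitting uses
    only the trials passed in. Pass precomputed `cov_tensors` (from
    :func:`compute_cov_tensors` on the same trials) to skip refiltering.
    """
    trials.require_two_classes()
    classes = tuple(int(c) for c in trials.classes)
    modes = build_modes(ranking, mode_sizes)
    if cov_tensors is None:
        cov_tensors = compute_cov_tensors(trials, band_grid, time_grid, filter_order)
    bank = _fit_bank_from_covs(
        cov_tensors, trials.labels, modes, band_grid, time_grid,
        m, shrinkage, classes, filter_order,
    )
    views = _views_from_covs(cov_tensors, trials.labels, bank)
    return bank, views


def transform_views(
    trials: EpochedTrials,
    bank: CSPFilterBank,
    cov_tensors: np.ndarray | None = None,
) -> list[ViewFeatures]:
    """Apply a fitted bank to (possibly unseen) trials; no refitting."""
    if cov_tensors is None:
        cov_tensors = compute_cov_tensors(
            trials, bank.band_grid, bank.time_grid, bank.filter_order
        )
    return _views_from_covs(cov_tensors, trials.labels, bank)
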