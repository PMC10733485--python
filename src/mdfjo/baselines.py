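"""Comparison decoders sharing the MDFJO primitives and CV protocol.

All baselines use the same preprocessing (CAR + broad 4-40 Hz band-pass),
the same biased trace-normalized CSP with shrinkage, the same RBF-SVM
with z-scored features, and — given the same master seed — the same
stratified outer folds as the full pipeline, enabling paired comparison.

* CSP: a single 4-40 Hz band over the full epoch.
* FBCSP + MIBIF: the 17-band filter bank over the full epoch; features
  ranked by histogram mutual information with the label, bands ranked by
  the mean MI of their features, top-4 bands kept.
* SFBCSP: Lasso on the band-feature matrix; surviving features feed the
  SVM; the penalty fraction gamma is tuned by inner CV.
* DFBCSP: Fisher ratio of one anchor channel's whole-epoch log band-power
  ranks the sub-bands; top-4 bands' CSP features feed the SVM.
* MSO: the multi-view L2,1 model restricted to a single time window
  (views = channel modes only), keeping all non-zero rows — i.e. MDFJO
  without the time-level sparsification step.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import Lasso
from sklearn.svm import SVC

from .channels import build_modes, fdc_scores, resolve_mode_sizes
from .config import Config
from .csp import _fit_bank_from_covs, _views_from_covs, compute_cov_tensors
from .io import EpochedTrials
from .pipeline import CVReport, _prepare, cross_validate, outer_folds
from .preprocess import BandGrid, TimeGrid, apply_car, bandpass, make_band_grid

__all__ = [
    "histogram_mi",
    "run_csp",
    "run_fbcsp_mibif",
    "run_sfbcsp",
    "run_dfbcsp",
    "run_mso",
]


# ---------------------------------------------------------------------------
# shared machinery: band-feature matrices over the full epoch
# ---------------------------------------------------------------------------


def _band_feature_setup(trials: EpochedTrials, config: Config, single_band: bool):
    """CAR + broad filter, then per-trial covariances for either the single
    broad band or the whole sub-band grid, over the full epoch."""
    pre = bandpass(apply_car(trials), *config.broad_band, config.filter_order)
    if single_band:
        band_grid = BandGrid(((config.broad_band),))
    else:
        band_grid = make_band_grid(config.fmin, config.fmax, config.band_width, config.band_step)
    time_grid = TimeGrid(((0.0, pre.duration),))
    covs = compute_cov_tensors(pre, band_grid, time_grid, config.filter_order)
    return pre, band_grid, time_grid, covs


def _fold_views(prep_pre, covs, band_grid, time_grid, tr, mode, config):
    """Fit CSP on the training trials of one fold for a single channel mode;
    return (bank, standardized train features fn, y encoder)."""
    labels = prep_pre.labels
    classes = tuple(int(c) for c in np.unique(labels[tr]))
    bank = _fit_bank_from_covs(
        covs[:, :, tr], labels[tr], [mode], band_grid, time_grid,
        config.m, config.shrinkage, classes, config.filter_order,
    )
    def features(idx):
        return _views_from_covs(covs[:, :, idx], labels[idx], bank)[0]
    return bank, features


def _zscore_pair(F_tr, F_te):
    mu, sd = F_tr.mean(axis=0), F_tr.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (F_tr - mu) / sd, (F_te - mu) / sd


def _svm_accuracy(F_tr, y_tr, F_te, y_te, config) -> float:
    F_tr, F_te = _zscore_pair(F_tr, F_te)
    clf = SVC(C=config.svm_c, gamma=config.svm_gamma, kernel="rbf").fit(F_tr, y_tr)
    return float(np.mean(clf.predict(F_te) == y_te))


def _mode_indices(prep_pre, logpower, tr, mode_size, config) -> np.ndarray:
    """Channel mode of one fold: FDC ranking on the training trials."""
    n = prep_pre.n_channels
    size = resolve_mode_sizes((mode_size,), n)[0]
    if size == n:
        return np.arange(n)
    ranking = fdc_scores(logpower[tr], prep_pre.labels[tr])
    return build_modes(ranking, (size,))[0]


def _logpower_for_fdc(pre, config):
    from .channels import logvar_segments

    seg_len = min(config.seg_len, pre.n_samples)
    return logvar_segments(pre, seg_len, config.seg_overlap)


# ---------------------------------------------------------------------------
# CSP baseline
# ---------------------------------------------------------------------------


def run_csp(
    trials: EpochedTrials,
    mode_size: int | str = "all",
    config: Config = Config(),
    seed: int = 0,
) -> CVReport:
    """Plain CSP (m filter pairs, broad band, full epoch) + SVM."""
    trials.require_two_classes()
    pre, band_grid, time_grid, covs = _band_feature_setup(trials, config, single_band=True)
    logpower = _logpower_for_fdc(pre, config)
    accs = []
    for tr, te in outer_folds(pre.labels, config.n_folds, seed):
        mode = _mode_indices(pre, logpower, tr, mode_size, config)
        bank, features = _fold_views(pre, covs, band_grid, time_grid, tr, mode, config)
        v_tr, v_te = features(tr), features(te)
        accs.append(_svm_accuracy(v_tr.X, v_tr.y, v_te.X, v_te.y, config))
    return CVReport(method=f"csp_{mode_size}", fold_accuracies=tuple(accs), seed=seed)


# ---------------------------------------------------------------------------
# FBCSP + MIBIF
# ---------------------------------------------------------------------------


def histogram_mi(x: np.ndarray, labels: np.ndarray, n_bins: int = 8) -> float:
    """Plug-in mutual information (nats) between a scalar feature and the
    class label, with equal-frequency binning of the feature."""
    x = np.asarray(x, dtype=float)
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 2:
        return 0.0
    b = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)
    classes = np.unique(labels)
    joint = np.zeros((len(edges) - 1, len(classes)))
    for ci, c in enumerate(classes):
        joint[:, ci] = np.bincount(b[labels == c], minlength=len(edges) - 1)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (px * py))
    return float(np.nansum(terms))


def mibif_band_ranking(X: np.ndarray, labels: np.ndarray, n_per_band: int) -> np.ndarray:
    """Bands ranked by the mean MI of their features, descending."""
    mi = np.array([histogram_mi(X[:, j], labels) for j in range(X.shape[1])])
    band_mi = mi.reshape(-1, n_per_band).mean(axis=1)
    return np.argsort(-band_mi, kind="stable")


def run_fbcsp_mibif(
    trials: EpochedTrials,
    mode_size: int | str = "all",
    config: Config = Config(),
    seed: int = 0,
    n_bands_keep: int = 4,
) -> CVReport:
    """Filter-bank CSP with MIBIF band selection (top `n_bands_keep` bands)."""
    trials.require_two_classes()
    pre, band_grid, time_grid, covs = _band_feature_setup(trials, config, single_band=False)
    logpower = _logpower_for_fdc(pre, config)
    n_per_band = 2 * config.m
    accs = []
    for tr, te in outer_folds(pre.labels, config.n_folds, seed):
        mode = _mode_indices(pre, logpower, tr, mode_size, config)
        bank, features = _fold_views(pre, covs, band_grid, time_grid, tr, mode, config)
        v_tr, v_te = features(tr), features(te)
        order = mibif_band_ranking(v_tr.X, pre.labels[tr], n_per_band)
        keep = np.sort(order[:n_bands_keep])
        cols = np.concatenate([np.arange(b * n_per_band, (b + 1) * n_per_band) for b in keep])
        accs.append(_svm_accuracy(v_tr.X[:, cols], v_tr.y, v_te.X[:, cols], v_te.y, config))
    return CVReport(method=f"fbcsp_{mode_size}", fold_accuracies=tuple(accs), seed=seed)


# ---------------------------------------------------------------------------
# SFBCSP (Lasso band-feature selection)
# ---------------------------------------------------------------------------


def _lasso_support(F: np.ndarray, y: np.ndarray, gamma: float) -> np.ndarray:
    """Non-zero-coefficient features of an L1 least-squares fit; `gamma` is a
    fraction of the smallest penalty giving an all-zero coefficient vector."""
    if gamma <= 0:
        return np.arange(F.shape[1])
    alpha_max = np.abs(F.T @ y).max() / len(y)
    lasso = Lasso(alpha=gamma * alpha_max, max_iter=5000)
    lasso.fit(F, y)
    return np.flatnonzero(lasso.coef_ != 0)


def default_gamma_grid() -> tuple[float, ...]:
    return tuple(round(0.01 * i, 2) for i in range(101))


def run_sfbcsp(
    trials: EpochedTrials,
    mode_size: int | str = "all",
    config: Config = Config(),
    seed: int = 0,
    gamma_grid: tuple[float, ...] | None = None,
) -> CVReport:
    """Sparse filter-band CSP: Lasso feature selection, gamma by inner CV."""
    trials.require_two_classes()
    from sklearn.model_selection import StratifiedKFold

    gamma_grid = default_gamma_grid() if gamma_grid is None else tuple(gamma_grid)
    pre, band_grid, time_grid, covs = _band_feature_setup(trials, config, single_band=False)
    logpower = _logpower_for_fdc(pre, config)
    accs = []
    for f, (tr, te) in enumerate(outer_folds(pre.labels, config.n_folds, seed)):
        mode = _mode_indices(pre, logpower, tr, mode_size, config)
        inner = StratifiedKFold(
            config.inner_folds, shuffle=True, random_state=(seed * 1000003 + f) % 2**31
        )
        acc_g = np.zeros(len(gamma_grid))
        valid = np.ones(len(gamma_grid), dtype=bool)
        for tr_rel, va_rel in inner.split(np.zeros(len(tr)), pre.labels[tr]):
            itr, iva = tr[tr_rel], tr[va_rel]
            bank, features = _fold_views(pre, covs, band_grid, time_grid, itr, mode, config)
            v_itr, v_iva = features(itr), features(iva)
            F_itr, F_iva = _zscore_pair(v_itr.X, v_iva.X)
            cache: dict[tuple, float] = {}  # identical supports share one SVM fit
            for g, gamma in enumerate(gamma_grid):
                sup = _lasso_support(F_itr, v_itr.y, gamma)
                if sup.size == 0:
                    valid[g] = False
                    continue
                key = tuple(sup)
                if key not in cache:
                    cache[key] = _svm_accuracy(
                        v_itr.X[:, sup], v_itr.y, v_iva.X[:, sup], v_iva.y, config
                    )
                acc_g[g] += cache[key]
        acc_g /= config.inner_folds
        acc_g[~valid] = -np.inf
        if not valid.any():
            raise ValueError("every gamma zeroed all features; decrease gamma")
        best = acc_g.max()
        gamma = gamma_grid[int(np.flatnonzero(acc_g >= best - 1e-12)[-1])]
        bank, features = _fold_views(pre, covs, band_grid, time_grid, tr, mode, config)
        v_tr, v_te = features(tr), features(te)
        F_tr_std, _ = _zscore_pair(v_tr.X, v_te.X)
        sup = _lasso_support(F_tr_std, v_tr.y, gamma)
        if sup.size == 0:
            raise ValueError(f"gamma={gamma} zeroed all features; decrease gamma")
        accs.append(_svm_accuracy(v_tr.X[:, sup], v_tr.y, v_te.X[:, sup], v_te.y, config))
    return CVReport(method=f"sfbcsp_{mode_size}", fold_accuracies=tuple(accs), seed=seed)


# ---------------------------------------------------------------------------
# DFBCSP (anchor-channel Fisher band selection)
# ---------------------------------------------------------------------------


def fisher_band_scores(covs: np.ndarray, labels: np.ndarray, anchor: int) -> np.ndarray:
    """Fisher ratio per sub-band of the anchor channel's whole-epoch log
    band-power. `covs` is the (bands, 1, trials, C, C) tensor."""
    classes = np.unique(labels)
    logp = np.log(covs[:, 0, :, anchor, anchor])  # (bands, trials)
    p1, p2 = logp[:, labels == classes[0]], logp[:, labels == classes[1]]
    return (p1.mean(axis=1) - p2.mean(axis=1)) ** 2 / (
        p1.var(axis=1, ddof=1) + p2.var(axis=1, ddof=1)
    )


def run_dfbcsp(
    trials: EpochedTrials,
    anchor_channel: str = "C3",
    config: Config = Config(),
    seed: int = 0,
    n_bands_keep: int = 4,
) -> CVReport:
    """Discriminative filter-bank CSP: anchor-channel Fisher band ranking."""
    trials.require_two_classes()
    if anchor_channel not in trials.channel_names:
        raise ValueError(f"anchor channel {anchor_channel!r} not in {trials.channel_names}")
    anchor = trials.channel_names.index(anchor_channel)
    pre, band_grid, time_grid, covs = _band_feature_setup(trials, config, single_band=False)
    n_per_band = 2 * config.m
    mode = np.arange(pre.n_channels)
    accs = []
    for tr, te in outer_folds(pre.labels, config.n_folds, seed):
        scores = fisher_band_scores(covs[:, :, tr], pre.labels[tr], anchor)
        keep = np.sort(np.argsort(-scores, kind="stable")[:n_bands_keep])
        bank, features = _fold_views(pre, covs, band_grid, time_grid, tr, mode, config)
        v_tr, v_te = features(tr), features(te)
        cols = np.concatenate([np.arange(b * n_per_band, (b + 1) * n_per_band) for b in keep])
        accs.append(_svm_accuracy(v_tr.X[:, cols], v_tr.y, v_te.X[:, cols], v_te.y, config))
    return CVReport(method="dfbcsp", fold_accuracies=tuple(accs), seed=seed)


# ---------------------------------------------------------------------------
# MSO (single-window multi-view optimization)
# ---------------------------------------------------------------------------


def run_mso(
    trials: EpochedTrials,
    window: tuple[float, float] = (0.5, 2.5),
    config: Config = Config(),
    seed: int = 0,
) -> CVReport:
    """Multi-scale optimization: the multi-view model on one time window,
    keeping every non-zero row (no time-level sparsification)."""
    cfg = config.updated(time_windows=(tuple(window),), fixed_ns="all")
    report = cross_validate(trials, cfg, seed)
    report.method = "mso"
    return report
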