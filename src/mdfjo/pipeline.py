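"""End-to-end multi-domain feature joint optimization (MDFJO).

The fitted pipeline is: common average reference and broad 4-40 Hz
band-pass; FDC channel ranking (on training trials only) defining the
nested channel modes; per-view CSP feature matrices over the sub-band
and time-window grids; nested-CV selection of the L2,1 penalty fraction
lambda and the time-level truncation Ns; the L2,1 solve on the full
training set at the chosen lambda; the sparsification step; and an
RBF-kernel SVM on the assembled, z-scored features.

Hyperparameter selection uses inner stratified 5-fold accuracy only on
the training folds — the outer test fold never touches any fitted
component. Lambda ties resolve toward the largest lambda (sparser
support at equal accuracy); Ns ties toward the smallest Ns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .channels import ChannelRanking, build_modes, fdc_scores, logvar_segments, resolve_mode_sizes
from .config import Config
from .csp import (
    CSPFilterBank,
    ViewFeatures,
    _fit_bank_from_covs,
    _views_from_covs,
    compute_cov_tensors,
)
from .io import EpochedTrials
from .multiview import MultiViewWeights, l21_solve
from .preprocess import BandGrid, TimeGrid, apply_car, bandpass, make_band_grid, make_time_grid
from .selection import SparseSelection, assemble_features, candidate_pairs, sparsify

__all__ = [
    "FittedModel",
    "CVReport",
    "DiscriminabilityScore",
    "fit",
    "predict",
    "cross_validate",
    "tune_hyperparams",
    "r_squared",
]


@dataclass(frozen=True)
class DiscriminabilityScore:
    """Squared, sample-size-weighted standardized mean difference r^2."""

    value: float
    n1: int
    n2: int


def r_squared(X1, X2) -> DiscriminabilityScore:
    """Discriminability of two feature/power vectors:

    r^2 = ( sqrt(L1 L2)/(L1+L2) * (mean(X1) - mean(X2)) / std(X1 u X2) )^2

    with the sample (ddof=1) standard deviation of the concatenation.
    """
    X1 = np.asarray(X1, dtype=float).ravel()
    X2 = np.asarray(X2, dtype=float).ravel()
    if X1.size < 1 or X2.size < 1:
        raise ValueError("both vectors must be non-empty")
    pooled = np.concatenate([X1, X2])
    sd = pooled.std(ddof=1)
    if sd == 0:
        raise ValueError("zero pooled standard deviation")
    L1, L2 = X1.size, X2.size
    r = np.sqrt(L1 * L2) / (L1 + L2) * (X1.mean() - X2.mean()) / sd
    return DiscriminabilityScore(value=float(r**2), n1=L1, n2=L2)


@dataclass
class CVReport:
    """Outer cross-validation summary."""

    method: str
    fold_accuracies: tuple[float, ...]
    chosen: tuple[tuple[float, int], ...] = ()  # per-fold (lam, ns); empty for baselines
    n_selected: tuple[int, ...] = ()
    seed: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "fold_accuracies": list(self.fold_accuracies),
            "mean": self.mean,
            "sd": self.sd,
            "chosen": [list(c) for c in self.chosen],
            "n_selected": list(self.n_selected),
            "seed": self.seed,
        }


@dataclass
class FittedModel:
    """Everything needed to transform and classify unseen trials."""

    config: Config
    channel_names: tuple[str, ...]
    fs: float
    n_samples: int
    band_grid: BandGrid
    time_grid: TimeGrid
    ranking: ChannelRanking
    mode_sizes: tuple[int, ...]
    bank: CSPFilterBank
    view_means: list[np.ndarray]
    view_stds: list[np.ndarray]
    weights: MultiViewWeights
    selection: SparseSelection
    svm: SVC
    lam: float
    ns: int
    seed: int
    train_features: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# internal prepared representation: label-independent per-trial quantities
# computed once and sliced per CV fold
# ---------------------------------------------------------------------------


@dataclass
class _Prepared:
    trials: EpochedTrials  # CAR + broad band-passed
    covs: np.ndarray  # (bands, windows, trials, C, C)
    logpower: np.ndarray  # (trials, C, segments) for FDC
    band_grid: BandGrid
    time_grid: TimeGrid


def _prepare(trials: EpochedTrials, config: Config) -> _Prepared:
    pre = bandpass(apply_car(trials), *config.broad_band, config.filter_order)
    band_grid = make_band_grid(config.fmin, config.fmax, config.band_width, config.band_step)
    if config.time_windows is not None:
        time_grid = TimeGrid(tuple(tuple(w) for w in config.time_windows))
    else:
        time_grid = make_time_grid(pre.duration, config.win_s, config.time_step_s)
    covs = compute_cov_tensors(pre, band_grid, time_grid, config.filter_order)
    seg_len = min(config.seg_len, pre.n_samples)
    logpower = logvar_segments(pre, seg_len, config.seg_overlap)
    return _Prepared(pre, covs, logpower, band_grid, time_grid)


def _standardize_fit(views: list[ViewFeatures]):
    means = [v.X.mean(axis=0) for v in views]
    stds = []
    for v in views:
        s = v.X.std(axis=0)
        s[s == 0] = 1.0
        stds.append(s)
    return means, stds


def _standardize_apply(views, means, stds) -> list[ViewFeatures]:
    return [
        ViewFeatures(X=(v.X - mu) / sd, y=v.y, index=v.index)
        for v, mu, sd in zip(views, means, stds)
    ]


def _make_svm(config: Config) -> SVC:
    return SVC(C=config.svm_c, gamma=config.svm_gamma, kernel="rbf")


def _ns_grid(config: Config, n_views: int) -> list[int]:
    if config.fixed_ns == "all":
        return [n_views]
    if config.fixed_ns is not None:
        return [int(config.fixed_ns)]
    return list(range(1, n_views + 1))


def _tune_on_indices(
    prep: _Prepared, idx: np.ndarray, config: Config, seed: int
) -> tuple[float, int, np.ndarray]:
    """Inner stratified CV over the lambda and Ns grids.

    Returns (lam, ns, accuracy table of shape (n_lam, n_ns)). Lambda values
    whose solution is all-zero in any inner fold are excluded; lambda = 1
    is degenerate by construction. Ties: largest lambda, then smallest Ns.
    """
    labels = prep.trials.labels[idx]
    n_channels = prep.trials.n_channels
    mode_sizes = resolve_mode_sizes(config.mode_sizes, n_channels)
    lam_grid = [l for l in config.lam_grid if l < 1.0]
    if not lam_grid:
        raise ValueError("lambda grid contains no value below 1")
    n_views_total = len(mode_sizes) * len(prep.time_grid)
    ns_grid = _ns_grid(config, n_views_total)

    if len(lam_grid) == 1 and len(ns_grid) == 1:
        return lam_grid[0], ns_grid[0], np.full((1, 1), np.nan)

    skf = StratifiedKFold(config.inner_folds, shuffle=True, random_state=seed % 2**31)
    acc = np.zeros((len(lam_grid), len(ns_grid)))
    degenerate = np.zeros(len(lam_grid), dtype=bool)
    n_folds = 0
    for tr_rel, va_rel in skf.split(np.zeros(len(idx)), labels):
        tr, va = idx[tr_rel], idx[va_rel]
        model_parts = _build_view_stack(prep, tr, config, mode_sizes)
        bank, tr_views, means, stds = model_parts
        va_views = _standardize_apply(
            _views_from_covs(prep.covs[:, :, va], prep.trials.labels[va], bank), means, stds
        )
        y_tr = tr_views[0].y
        y_va = va_views[0].y
        cache: dict[tuple, float] = {}  # identical candidate sets share one SVM fit
        for i, lam in enumerate(lam_grid):
            w = l21_solve(tr_views, lam, config.max_iter, config.tol)
            if w.nonzero_rows().size == 0:
                degenerate[i] = True
                continue
            sel = sparsify(w, ns=max(ns_grid))
            for j, ns in enumerate(ns_grid):
                pairs = candidate_pairs(sel.rows, sel.Q, sel.R, ns)
                if pairs not in cache:
                    F_tr = assemble_features(pairs, tr_views)
                    F_va = assemble_features(pairs, va_views)
                    clf = _make_svm(config).fit(F_tr, y_tr)
                    cache[pairs] = float(np.mean(clf.predict(F_va) == y_va))
                acc[i, j] += cache[pairs]
        n_folds += 1
    acc /= n_folds
    acc[degenerate] = -np.inf
    if np.all(degenerate):
        raise ValueError("every lambda on the grid yields an all-zero solution")
    best = acc.max()
    lam_ok = np.flatnonzero(acc.max(axis=1) >= best - 1e-12)
    i_star = lam_ok[-1]  # largest lambda attaining the max
    j_star = int(np.argmax(acc[i_star] >= best - 1e-12))  # smallest Ns at that lambda
    return lam_grid[i_star], ns_grid[j_star], acc


def _build_view_stack(prep: _Prepared, idx: np.ndarray, config: Config, mode_sizes):
    """Rank channels, fit the CSP bank and standardized views on `idx` trials."""
    labels = prep.trials.labels[idx]
    ranking = fdc_scores(prep.logpower[idx], labels)
    modes = build_modes(ranking, mode_sizes)
    covs = prep.covs[:, :, idx]
    classes = tuple(int(c) for c in np.unique(labels))
    bank = _fit_bank_from_covs(
        covs, labels, modes, prep.band_grid, prep.time_grid,
        config.m, config.shrinkage, classes, config.filter_order,
    )
    views = _views_from_covs(covs, labels, bank)
    means, stds = _standardize_fit(views)
    return bank, _standardize_apply(views, means, stds), means, stds


def _fit_on_indices(prep: _Prepared, idx: np.ndarray, config: Config, seed: int) -> FittedModel:
    labels = prep.trials.labels[idx]
    if np.unique(labels).size != 2:
        raise ValueError("fitting requires both classes in the training trials")
    counts = np.bincount(np.searchsorted(np.unique(labels), labels))
    if counts.min() < config.inner_folds:
        raise ValueError("too few trials per class for the inner folds")
    n_channels = prep.trials.n_channels
    mode_sizes = resolve_mode_sizes(config.mode_sizes, n_channels)

    lam, ns, _ = _tune_on_indices(prep, idx, config, seed)

    ranking = fdc_scores(prep.logpower[idx], labels)
    bank, std_views, means, stds = _build_view_stack(prep, idx, config, mode_sizes)
    weights = l21_solve(std_views, lam, config.max_iter, config.tol)
    # the inner-CV lambda can zero every row on the full training set (the
    # support boundary shifts slightly with n); step down the grid if so
    smaller = sorted((l for l in config.lam_grid if l < lam), reverse=True)
    while weights.nonzero_rows().size == 0 and smaller:
        lam = smaller.pop(0)
        weights = l21_solve(std_views, lam, config.max_iter, config.tol)
    if weights.nonzero_rows().size == 0:
        raise ValueError(f"lambda={lam} zeroed every feature row; decrease lambda")
    selection = sparsify(weights, ns=ns)
    F = assemble_features(selection.pairs, std_views)
    clf = _make_svm(config).fit(F, std_views[0].y)
    return FittedModel(
        config=config,
        channel_names=prep.trials.channel_names,
        fs=prep.trials.fs,
        n_samples=prep.trials.n_samples,
        band_grid=prep.band_grid,
        time_grid=prep.time_grid,
        ranking=ranking,
        mode_sizes=mode_sizes,
        bank=bank,
        view_means=means,
        view_stds=stds,
        weights=weights,
        selection=selection,
        svm=clf,
        lam=lam,
        ns=ns,
        seed=seed,
        train_features=F,
    )


def fit(trials: EpochedTrials, config: Config = Config(), seed: int = 0) -> FittedModel:
    """Fit the full MDFJO pipeline on `trials` (all of them as training data)."""
    trials.require_two_classes()
    prep = _prepare(trials, config)
    return _fit_on_indices(prep, np.arange(trials.n_trials), config, seed)


def tune_hyperparams(trials: EpochedTrials, config: Config = Config(), seed: int = 0):
    """Inner-CV selection of (lambda, Ns) on `trials`; returns (lam, ns)."""
    trials.require_two_classes()
    prep = _prepare(trials, config)
    lam, ns, _ = _tune_on_indices(prep, np.arange(trials.n_trials), config, seed)
    return lam, ns


def _predict_features(model: FittedModel, prep_covs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    views = _views_from_covs(prep_covs, labels, model.bank)
    std_views = _standardize_apply(views, model.view_means, model.view_stds)
    return assemble_features(model.selection.pairs, std_views)


def predict(model: FittedModel, trials: EpochedTrials) -> np.ndarray:
    """Classify unseen trials with a fitted model; returns class codes."""
    if trials.channel_names != model.channel_names:
        raise ValueError("channel names do not match the fitted model")
    pre = bandpass(apply_car(trials), *model.config.broad_band, model.config.filter_order)
    covs = compute_cov_tensors(pre, model.band_grid, model.time_grid, model.config.filter_order)
    F = _predict_features(model, covs, trials.labels)
    y_hat = model.svm.predict(F)
    c1, c2 = model.bank.class_order
    return np.where(y_hat > 0, c1, c2)


def outer_folds(labels: np.ndarray, n_folds: int, seed: int):
    """Shared stratified outer-fold assignment for MDFJO and all baselines."""
    skf = StratifiedKFold(n_folds, shuffle=True, random_state=seed % 2**31)
    return list(skf.split(np.zeros(len(labels)), labels))


def cross_validate(trials: EpochedTrials, config: Config = Config(), seed: int = 0) -> CVReport:
    """Outer stratified k-fold evaluation of the whole pipeline.

    Every fitted component — FDC ranking, CSP bank, standardization,
    solver, sparsification, SVM, and the inner-CV hyperparameter search —
    is recomputed from the training folds alone.
    """
    trials.require_two_classes()
    prep = _prepare(trials, config)
    accs, chosen, n_sel = [], [], []
    for f, (tr, te) in enumerate(outer_folds(trials.labels, config.n_folds, seed)):
        model = _fit_on_indices(prep, tr, config, (seed * 1000003 + f) % 2**31)
        F_te = _predict_features(model, prep.covs[:, :, te], trials.labels[te])
        y_hat = model.svm.predict(F_te)
        y_te = model.bank.encode_labels(trials.labels[te])
        accs.append(float(np.mean(y_hat == y_te)))
        chosen.append((model.lam, model.ns))
        n_sel.append(len(model.selection.pairs))
    return CVReport(
        method="mdfjo",
        fold_accuracies=tuple(accs),
        chosen=tuple(chosen),
        n_selected=tuple(n_sel),
        seed=seed,
    )
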