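"""Synthetic-benchmark drivers: recovery rates and method comparisons.

These routines run the full pipeline and the comparison decoders over
seeded replicates of the default synthetic ERD dataset and summarize
recovery of the planted structure (active channels, discriminative band)
and decoding accuracy. Used by the acceptance checks and reproduction
script; all randomness derives from the seeds passed in.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import baselines as bl
from .channels import rank_channels, resolve_mode_sizes
from .config import Config
from .multiview import l21_solve
from .pipeline import _build_view_stack, _prepare, _tune_on_indices, cross_validate
from .preprocess import apply_car, bandpass, make_band_grid
from .synth import SyntheticSpec, generate

__all__ = [
    "benchmark_config",
    "fdc_recovery_rate",
    "band_support_recovery_rate",
    "method_accuracies",
    "permutation_accuracies",
    "null_attenuation_accuracies",
]


def benchmark_config() -> Config:
    """Pipeline config for the 20-channel synthetic benchmark: nested
    channel modes of 8, 16 and all channels (the 16/32/all protocol scaled
    to the generator's channel count), everything else at defaults."""
    return Config(mode_sizes=(8, 16, "all"))


def fdc_recovery_rate(n_seeds: int = 100, seed0: int = 0) -> float:
    """Fraction of seeds where FDC ranks both active channels top-2."""
    hits = 0
    for s in range(n_seeds):
        spec = SyntheticSpec(seed=seed0 + s)
        trials, _ = generate(spec)
        pre = bandpass(apply_car(trials), 4, 40, 5)
        ranking = rank_channels(pre, 100, 0.5)
        hits += set(ranking.order[:2].tolist()) == set(spec.active_channels)
    return hits / n_seeds


def band_support_recovery_rate(n_seeds: int = 100, seed0: int = 0) -> float:
    """Fraction of seeds where the L2,1 support at the inner-CV-tuned
    lambda contains a feature row of the planted ERD band."""
    cfg = benchmark_config().updated(fixed_ns="all")
    hits = 0
    for s in range(n_seeds):
        spec = SyntheticSpec(seed=seed0 + s)
        trials, manifest = generate(spec)
        # rows of the grid band matching the planted band exactly
        grid = make_band_grid(cfg.fmin, cfg.fmax, cfg.band_width, cfg.band_step)
        exact = [b for b, band in enumerate(grid) if band == spec.erd_band]
        target_rows = {2 * b for b in exact} | {2 * b + 1 for b in exact}
        prep = _prepare(trials, cfg)
        idx = np.arange(trials.n_trials)
        lam, _, _ = _tune_on_indices(prep, idx, cfg, seed0 + s)
        mode_sizes = resolve_mode_sizes(cfg.mode_sizes, trials.n_channels)
        _, std_views, _, _ = _build_view_stack(prep, idx, cfg, mode_sizes)
        rows = set(l21_solve(std_views, lam).nonzero_rows().tolist())
        hits += bool(rows & target_rows)
    return hits / n_seeds


def method_accuracies(seeds, config: Config | None = None) -> dict[str, list[float]]:
    """Mean 5-fold accuracy per seed for the pipeline and every baseline,
    on the same per-seed dataset with shared outer folds."""
    cfg = benchmark_config() if config is None else config
    out: dict[str, list[float]] = {
        m: [] for m in ("mdfjo", "csp", "fbcsp", "sfbcsp", "dfbcsp", "mso")
    }
    for seed in seeds:
        trials, _ = generate(SyntheticSpec(seed=seed))
        out["mdfjo"].append(cross_validate(trials, cfg, seed).mean)
        out["csp"].append(bl.run_csp(trials, "all", cfg, seed).mean)
        out["fbcsp"].append(bl.run_fbcsp_mibif(trials, "all", cfg, seed).mean)
        out["sfbcsp"].append(bl.run_sfbcsp(trials, "all", cfg, seed).mean)
        out["dfbcsp"].append(bl.run_dfbcsp(trials, "C3", cfg, seed).mean)
        out["mso"].append(bl.run_mso(trials, (0.5, 2.5), cfg, seed).mean)
    return out


def permutation_accuracies(seeds) -> list[float]:
    """Pipeline CV accuracy with labels randomly permuted (chance control)."""
    cfg = benchmark_config()
    out = []
    for seed in seeds:
        trials, _ = generate(SyntheticSpec(seed=seed))
        rng = np.random.default_rng(seed)
        permuted = replace(trials, labels=rng.permutation(trials.labels))
        out.append(cross_validate(permuted, cfg, seed).mean)
    return out


def null_attenuation_accuracies(seeds) -> list[float]:
    """Pipeline CV accuracy when attenuation = 1 (no planted effect)."""
    cfg = benchmark_config()
    out = []
    for seed in seeds:
        trials, _ = generate(SyntheticSpec(attenuation=1.0, seed=seed))
        out.append(cross_validate(trials, cfg, seed).mean)
    return out
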