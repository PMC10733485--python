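"""Fisher-discriminant-criterion channel scoring and nested channel modes.

Each channel is scored by the Fisher discriminant criterion (FDC) of its
segment log-power: the epoch is cut into overlapping segments, the
log-variance of each segment is the feature, and per segment

    phi = (m1 - m2)^2 / (var(P1) + var(P2))

compares the two class distributions of that feature. A channel's score
is the maximum phi over its segments; channels are ranked descending and
the top-16 / top-32 / all-channel prefixes form the nested channel modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EpochedTrials

__all__ = ["ChannelRanking", "logvar_segments", "fdc_scores", "build_modes"]

DEFAULT_MODE_SIZES = (16, 32)  # "all" is appended per dataset


@dataclass(frozen=True)
class ChannelRanking:
    """Per-channel FDC scores and the descending-score channel order."""

    scores: np.ndarray
    order: np.ndarray

    def __post_init__(self) -> None:
        order = np.asarray(self.order)
        if sorted(order.tolist()) != list(range(len(self.scores))):
            raise ValueError("order must be a permutation of channel indices")


def segment_starts(n_samples: int, seg_len: int, overlap_frac: float) -> np.ndarray:
    """Start indices of overlapping segments covering [0, n_samples)."""
    if seg_len > n_samples:
        raise ValueError(f"segment length {seg_len} exceeds {n_samples} samples")
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap fraction must be in [0, 1)")
    step = max(1, int(round(seg_len * (1.0 - overlap_frac))))
    return np.arange(0, n_samples - seg_len + 1, step)


def logvar_segments(
    trials: EpochedTrials, seg_len: int = 100, overlap_frac: float = 0.5
) -> np.ndarray:
    """Log-power of overlapping rectangular segments.

    Returns an array ``(n_trials, n_channels, n_segments)`` with
    ``log(var(x))`` of each segment (biased variance, mean removed).
    """
    starts = segment_starts(trials.n_samples, seg_len, overlap_frac)
    segs = np.stack([trials.data[:, :, s : s + seg_len] for s in starts], axis=2)
    var = segs.var(axis=-1)
    if np.any(var <= 0):
        t, c, s = np.argwhere(var <= 0)[0]
        raise ValueError(f"zero-variance segment: trial {t}, channel {c}, segment {s}")
    return np.log(var)


def fdc_scores(
    logpower: np.ndarray, labels: np.ndarray, classes: tuple[int, int] | None = None
) -> ChannelRanking:
    """FDC channel ranking from segment log-powers.

    `logpower` is the ``(trials, channels, segments)`` array from
    :func:`logvar_segments`. Per channel and segment the Fisher ratio of
    the two class distributions is computed; the max over segments is the
    channel score. Ties break toward the lower channel index.
    """
    labels = np.asarray(labels)
    if classes is None:
        classes = tuple(np.unique(labels))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    p1 = logpower[labels == classes[0]]
    p2 = logpower[labels == classes[1]]
    if len(p1) < 2 or len(p2) < 2:
        raise ValueError("each class needs >= 2 trials for within-class variance")
    m1, m2 = p1.mean(axis=0), p2.mean(axis=0)
    v1, v2 = p1.var(axis=0, ddof=1), p2.var(axis=0, ddof=1)
    phi = (m1 - m2) ** 2 / (v1 + v2)  # (channels, segments)
    scores = phi.max(axis=1)
    order = np.argsort(-scores, kind="stable")
    return ChannelRanking(scores=scores, order=order)


def rank_channels(
    trials: EpochedTrials, seg_len: int = 100, overlap_frac: float = 0.5
) -> ChannelRanking:
    """Convenience: :func:`logvar_segments` then :func:`fdc_scores`."""
    return fdc_scores(logvar_segments(trials, seg_len, overlap_frac), trials.labels)


def build_modes(ranking: ChannelRanking, sizes: tuple[int, ...]) -> list[np.ndarray]:
    """Nested channel modes: the top-`size` prefixes of the FDC order."""
    n = len(ranking.scores)
    sizes = tuple(int(s) for s in sizes)
    if list(sizes) != sorted(set(sizes)):
        raise ValueError(f"mode sizes must be strictly increasing, got {sizes}")
    if sizes[-1] > n:
        raise ValueError(f"mode size {sizes[-1]} exceeds {n} channels")
    return [ranking.order[:s].copy() for s in sizes]


def resolve_mode_sizes(sizes, n_channels: int) -> tuple[int, ...]:
    """Replace the sentinel 'all' (or None) with the channel count, drop
    sizes that do not fit, and always include the all-channel mode."""
    out = []
    for s in sizes:
        s = n_channels if s in ("all", None) else int(s)
        if s <= n_channels and s not in out:
            out.append(s)
    if n_channels not in out:
        out.append(n_channels)
    return tuple(sorted(out))
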