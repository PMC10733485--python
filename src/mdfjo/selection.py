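"""Time-level feature sparsification of the multi-view weight matrix.

The L2,1 solution selects whole feature rows across all views. The
sparsification step refines that selection per view: restrict U to its
non-zero rows (matrix Q), sort each row's views by absolute weight
(matrix R of view indices), and keep for every row only its Ns
strongest views, superposing R column by column. The candidate sets are
therefore nested in Ns; the accuracy of each candidate set is measured
and the smallest Ns attaining the maximum is kept.

Zero entries inside a non-zero row are never selected: a feature the
model assigned zero weight in some view was not chosen for that view.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .csp import ViewFeatures
from .multiview import MultiViewWeights

__all__ = ["SparseSelection", "candidate_pairs", "sparsify", "assemble_features"]

Pair = tuple[int, int]  # (feature row, view)


@dataclass(frozen=True)
class SparseSelection:
    """Outcome of the sparsification strategy.

    ``rows`` are the non-zero rows of U; ``Q`` their true weights
    (len(rows) x n_views); ``R[i]`` the view indices of row i sorted by
    |Q| descending; ``ns`` the number of leading columns of R retained;
    ``pairs`` the final (feature row, view) set, sorted by row then view.
    """

    rows: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    ns: int
    pairs: tuple[Pair, ...]
    accuracy_curve: np.ndarray | None = None


def _qr(weights: MultiViewWeights) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rows = weights.nonzero_rows()
    if rows.size == 0:
        raise ValueError("U has no non-zero rows; decrease lam")
    Q = weights.U[rows]
    R = np.argsort(-np.abs(Q), axis=1, kind="stable")
    return rows, Q, R


def candidate_pairs(rows: np.ndarray, Q: np.ndarray, R: np.ndarray, ns: int) -> tuple[Pair, ...]:
    """Pair set for a given Ns: each row's `ns` strongest views, zeros excluded."""
    pairs = []
    for i, row in enumerate(rows):
        for j in range(min(ns, R.shape[1])):
            v = int(R[i, j])
            if Q[i, v] != 0:
                pairs.append((int(row), v))
    return tuple(sorted(pairs))


def sparsify(
    weights: MultiViewWeights,
    evaluate: Callable[[tuple[Pair, ...]], float] | None = None,
    ns: int | None = None,
    ns_grid: Sequence[int] | None = None,
) -> SparseSelection:
    """Choose the per-row view truncation Ns and the final feature pairs.

    Either `evaluate` (accuracy of a candidate pair set; the smallest Ns
    attaining the maximum accuracy wins) or a fixed `ns` must be given.
    """
    rows, Q, R = _qr(weights)
    n_views = Q.shape[1]
    if ns is not None:
        ns = int(ns)
        return SparseSelection(rows, Q, R, ns, candidate_pairs(rows, Q, R, ns))
    if evaluate is None:
        raise ValueError("either `evaluate` or `ns` is required")
    grid = list(ns_grid) if ns_grid is not None else list(range(1, n_views + 1))
    curve = np.array([evaluate(candidate_pairs(rows, Q, R, n)) for n in grid])
    best = grid[int(np.argmax(curve))]  # argmax returns the first (smallest) maximizer
    return SparseSelection(rows, Q, R, best, candidate_pairs(rows, Q, R, best), curve)


def assemble_features(pairs: Sequence[Pair], views: list[ViewFeatures]) -> np.ndarray:
    """Gather the selected (feature row, view) columns into one N x |pairs| matrix.

    Column order follows `pairs` sorted by row then view.
    """
    if len(pairs) == 0:
        raise ValueError("empty feature selection")
    ordered = sorted(pairs)
    rows = np.array([p[0] for p in ordered])
    vs = np.array([p[1] for p in ordered])
    if vs.min() < 0 or vs.max() >= len(views):
        raise IndexError(f"view index out of range in {ordered}")
    if rows.min() < 0 or rows.max() >= views[0].X.shape[1]:
        raise IndexError(f"feature row out of range in {ordered}")
    out = np.empty((views[0].X.shape[0], len(ordered)))
    for v in np.unique(vs):
        sel = vs == v
        out[:, sel] = views[v].X[:, rows[sel]]
    return out
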