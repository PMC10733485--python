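"""Pipeline configuration: one flat dataclass, YAML-serializable.

Defaults follow the standard motor-imagery protocol: 5th-order 4-40 Hz
broad band-pass after CAR; 17 overlapping 4 Hz sub-bands (2 Hz step);
2 s time windows every 0.5 s; nested channel modes of 16, 32 and all
channels; one CSP filter pair per band; the lambda grid {0, 0.1, ..., 1}
as fractions of lambda_max; 5-fold outer and inner cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import yaml

__all__ = ["Config", "load_config"]


def _lam_default() -> tuple[float, ...]:
    return tuple(round(0.1 * i, 1) for i in range(11))


@dataclass(frozen=True)
class Config:
    # preprocessing
    broad_band: tuple[float, float] = (4.0, 40.0)
    filter_order: int = 5
    # band / time grids
    fmin: float = 4.0
    fmax: float = 40.0
    band_width: float = 4.0
    band_step: float = 2.0
    win_s: float = 2.0
    time_step_s: float = 0.5
    time_windows: tuple[tuple[float, float], ...] | None = None  # explicit override
    # channel modes
    mode_sizes: tuple = (16, 32, "all")
    seg_len: int = 100
    seg_overlap: float = 0.5
    # CSP
    m: int = 1
    shrinkage: float = 0.05
    # L2,1 solver
    lam_grid: tuple[float, ...] = field(default_factory=_lam_default)
    tol: float = 1e-6
    max_iter: int = 1000
    # sparsification; None -> tune Ns over {1..S*T}; "all" -> keep every view
    fixed_ns: int | str | None = None
    # classifier
    svm_c: float = 1.0
    svm_gamma: float | str = "scale"
    # cross-validation
    n_folds: int = 5
    inner_folds: int = 5

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        with open(path, "w") as f:
            yaml.safe_dump(d, f, sort_keys=False)

    def updated(self, **kwargs) -> "Config":
        return replace(self, **kwargs)


def _tuplify(x):
    if isinstance(x, list):
        return tuple(_tuplify(v) for v in x)
    return x


def load_config(path: str) -> Config:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return Config(**{k: _tuplify(v) for k, v in raw.items()})
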