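"""Epoched-trial container and HDF5/NPZ readers and writers.

The unit of analysis throughout the package is a cue-aligned epoch:
``data`` has shape ``(n_trials, n_channels, n_samples)`` in microvolts,
with one integer class code per trial and a common sampling rate. This
axis order is fixed everywhere and asserted at the I/O boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = ["EpochedTrials", "FormatError", "read_trials", "write_trials"]


class FormatError(ValueError):
    """A container file is missing a required dataset or attribute."""


@dataclass(frozen=True)
class EpochedTrials:
    """Two-class epoched EEG trials.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Signal in microvolts.
    labels : ndarray of int, shape (n_trials,)
        Class codes; a dataset used for fitting must contain exactly two
        distinct values (conventionally 1 and 2).
    fs : float
        Sampling rate in Hz.
    channel_names : tuple of str
        Ordered 10-20-system channel labels.
    epoch_start : float
        Epoch start in seconds relative to cue onset.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    epoch_start: float = 0.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "channel_names", tuple(str(c) for c in self.channel_names))
        if data.ndim != 3:
            raise ValueError(f"data must be 3-axis (trials, channels, samples), got ndim={data.ndim}")
        if labels.ndim != 1 or labels.shape[0] != data.shape[0]:
            raise ValueError(
                f"labels length {labels.shape} does not match {data.shape[0]} trials"
            )
        if len(self.channel_names) != data.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {data.shape[1]} channels"
            )
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(data)):
            raise ValueError("data contains NaN or Inf")

    # -- shape accessors ------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration(self) -> float:
        """Epoch length in seconds."""
        return self.n_samples / self.fs

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def require_two_classes(self) -> None:
        """Raise unless exactly two distinct class codes are present."""
        classes = self.classes
        if classes.size != 2:
            raise ValueError(
                f"fitting requires exactly 2 classes, found {classes.size}: {classes.tolist()}"
            )

    def with_data(self, data: np.ndarray) -> "EpochedTrials":
        """Copy of self with `data` replaced (metadata preserved)."""
        return replace(self, data=data)

    def select_trials(self, idx) -> "EpochedTrials":
        return replace(self, data=self.data[idx], labels=self.labels[idx])

    def select_channels(self, idx) -> "EpochedTrials":
        idx = np.asarray(idx)
        return replace(
            self,
            data=self.data[:, idx, :],
            channel_names=tuple(self.channel_names[i] for i in idx),
        )


_REQUIRED_DATASETS = ("data", "labels")
_REQUIRED_ATTRS = ("fs", "channel_names", "epoch_start")


def read_trials(path: str | os.PathLike) -> EpochedTrials:
    """Read an :class:`EpochedTrials` container from HDF5 (``.h5``) or NPZ.

    The container must hold datasets ``data`` (trials x channels x samples)
    and ``labels``, plus attributes/keys ``fs``, ``channel_names`` and
    ``epoch_start``. Validation runs before any numerics.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.endswith(".npz"):
        return _read_npz(path)
    return _read_hdf5(path)


def _read_hdf5(path: str) -> EpochedTrials:
    with h5py.File(path, "r") as f:
        for name in _REQUIRED_DATASETS:
            if name not in f:
                raise FormatError(f"{path}: missing dataset '{name}'")
        for name in _REQUIRED_ATTRS:
            if name not in f.attrs:
                raise FormatError(f"{path}: missing attribute '{name}'")
        names = [c.decode() if isinstance(c, bytes) else str(c) for c in f.attrs["channel_names"]]
        return EpochedTrials(
            data=f["data"][()],
            labels=f["labels"][()],
            fs=float(f.attrs["fs"]),
            channel_names=tuple(names),
            epoch_start=float(f.attrs["epoch_start"]),
        )


def _read_npz(path: str) -> EpochedTrials:
    with np.load(path, allow_pickle=False) as f:
        for name in _REQUIRED_DATASETS + _REQUIRED_ATTRS:
            if name not in f.files:
                raise FormatError(f"{path}: missing key '{name}'")
        return EpochedTrials(
            data=f["data"],
            labels=f["labels"],
            fs=float(f["fs"]),
            channel_names=tuple(str(c) for c in f["channel_names"]),
            epoch_start=float(f["epoch_start"]),
        )


def write_trials(
    trials: EpochedTrials, path: str | os.PathLike, *, overwrite: bool = False
) -> str:
    """Write `trials` to HDF5 (default) or NPZ, chosen by file extension.

    Data are stored as float32 (single precision); labels as int8.
    Refuses to overwrite an existing file unless ``overwrite=True``.
    """
    path = os.fspath(path)
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    if path.endswith(".npz"):
        np.savez(
            path,
            data=trials.data.astype(np.float32),
            labels=trials.labels.astype(np.int8),
            fs=np.float64(trials.fs),
            channel_names=np.array(trials.channel_names),
            epoch_start=np.float64(trials.epoch_start),
        )
        return path
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=trials.data.astype(np.float32))
        f.create_dataset("labels", data=trials.labels.astype(np.int8))
        f.attrs["fs"] = float(trials.fs)
        f.attrs["channel_names"] = [c.encode() for c in trials.channel_names]
        f.attrs["epoch_start"] = float(trials.epoch_start)
    return path
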