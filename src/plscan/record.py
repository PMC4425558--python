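"""The universal multichannel signal container and its file formats.

A :class:`TimeSeriesRecord` holds a real ``(n_channels, n_samples)`` matrix
together with the sampling rate, channel labels and a free-form provenance
mapping.  Two on-disk representations are supported:

* HDF5 — dataset ``/data``, scalar attribute ``fs``, dataset ``/labels``
  and the provenance mapping JSON-serialized under ``/meta``;
* CSV — one column per channel with the labels as header row, plus a JSON
  sidecar (``<path>.json``) carrying ``fs`` and ``meta``.  Intended for
  small, human-readable fixtures only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np

from .errors import ArgumentError

__all__ = ["TimeSeriesRecord", "load_record", "save_record"]


@dataclass
class TimeSeriesRecord:
    """Multichannel real-valued time series sampled at a fixed rate.

    Parameters
    ----------
    data
        Real matrix of shape ``(n_channels, n_samples)``; arbitrary units.
    fs
        Sampling rate in Hz, strictly positive.
    labels
        One unique name per channel.
    meta
        Free-form provenance mapping (generator parameters, preprocessing
        history).  Copied defensively on construction.
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ArgumentError("data must be a 2-D (n_channels, n_samples) matrix")
        n_ch, n_s = self.data.shape
        if n_ch < 1 or n_s < 2:
            raise ArgumentError("need at least 1 channel and 2 samples")
        if not np.all(np.isfinite(self.data)):
            raise ArgumentError("data contains non-finite values")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ArgumentError("fs must be finite and > 0")
        self.fs = float(self.fs)
        self.labels = [str(x) for x in self.labels]
        if len(self.labels) != n_ch:
            raise ArgumentError(
                f"got {len(self.labels)} labels for {n_ch} channels"
            )
        if len(set(self.labels)) != n_ch:
            raise ArgumentError("channel labels must be unique")
        self.meta = dict(self.meta)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.fs

    def replace_data(
        self, data: np.ndarray, history_entry: Mapping[str, Any] | None = None
    ) -> "TimeSeriesRecord":
        """Return a new record with ``data`` swapped and, optionally, a
        preprocessing history entry appended to ``meta['history']``."""
        meta = dict(self.meta)
        if history_entry is not None:
            meta["history"] = list(meta.get("history", [])) + [dict(history_entry)]
        return TimeSeriesRecord(data=data, fs=self.fs, labels=list(self.labels), meta=meta)


def save_record(record: TimeSeriesRecord, path: str | Path) -> None:
    """Write a record to HDF5 (``.h5``/``.hdf5``) or CSV (anything else)."""
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        _save_hdf5(record, path)
    else:
        _save_csv(record, path)


def load_record(path: str | Path) -> TimeSeriesRecord:
    """Read a record previously written by :func:`save_record`."""
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        return _load_hdf5(path)
    return _load_csv(path)


def _save_hdf5(record: TimeSeriesRecord, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        dset = f.create_dataset("data", data=record.data)
        dset.attrs["fs"] = record.fs
        f.attrs["fs"] = record.fs
        f.create_dataset("labels", data=np.array(record.labels, dtype=object),
                         dtype=h5py.string_dtype())
        f.create_dataset("meta", data=json.dumps(record.meta, default=str))


def _load_hdf5(path: Path) -> TimeSeriesRecord:
    import h5py

    with h5py.File(path, "r") as f:
        data = f["data"][()]
        fs = float(f.attrs["fs"])
        labels = [x.decode() if isinstance(x, bytes) else str(x) for x in f["labels"][()]]
        meta = json.loads(f["meta"][()])
    return TimeSeriesRecord(data=data, fs=fs, labels=labels, meta=meta)


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _save_csv(record: TimeSeriesRecord, path: Path) -> None:
    header = ",".join(record.labels)
    np.savetxt(path, record.data.T, delimiter=",", header=header, comments="")
    _sidecar(path).write_text(
        json.dumps({"fs": record.fs, "meta": record.meta}, default=str)
    )


def _load_csv(path: Path) -> TimeSeriesRecord:
    with open(path) as f:
        labels = f.readline().strip().split(",")
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2).T
    side = json.loads(_sidecar(path).read_text())
    return TimeSeriesRecord(data=data, fs=side["fs"], labels=labels, meta=side.get("meta", {}))


def _ensure_labels(labels: Sequence[str] | None, n_channels: int) -> list[str]:
    """Default channel labels ``ch00, ch01, ...`` when none are supplied."""
    if labels is None:
        width = max(2, len(str(n_channels - 1)))
        return [f"ch{i:0{width}d}" for i in range(n_channels)]
    return [str(x) for x in labels]
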