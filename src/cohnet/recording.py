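"""Multichannel EEG recording container and plain-text I/O.

A :class:`Recording` is a channels x samples matrix in microvolts with a
sampling rate and an ordered electrode-label list.  Recordings are stored
on disk as a comma-separated matrix (header row = electrode labels, one
row per sample) plus a small JSON sidecar carrying the sampling rate, so
every artifact remains inspectable with standard tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class Recording:
    """One subject/task multichannel EEG trace.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` array, microvolts.
    fs
        Sampling rate in Hz.
    labels
        Ordered electrode names, one per row of ``data``.
    """

    data: np.ndarray
    fs: float
    labels: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = tuple(self.labels)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.labels):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.labels)} labels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("electrode labels must be unique")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return the sample vector of one electrode."""
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None
        return self.data[idx]

    def pick(self, labels: list[str] | tuple[str, ...]) -> "Recording":
        """Sub-recording restricted to ``labels``, in the given order."""
        missing = [lab for lab in labels if lab not in self.labels]
        if missing:
            raise KeyError(
                f"channel(s) {missing} not in recording; available: "
                f"{', '.join(self.labels)}"
            )
        idx = [self.labels.index(lab) for lab in labels]
        return Recording(self.data[idx].copy(), self.fs, tuple(labels), dict(self.meta))

    def copy_with(self, data: np.ndarray) -> "Recording":
        """Same montage/rate, new sample matrix."""
        return replace(self, data=data)


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as CSV (labels header, rows = samples) + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=list(rec.labels))
    df.to_csv(path, index=False, float_format="%.6f")
    sidecar = {"fs": rec.fs, "labels": list(rec.labels), **rec.meta}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(path: str | Path, fs: float | None = None) -> Recording:
    """Read a recording written by :func:`write_recording`.

    The sampling rate is taken from the JSON sidecar unless given explicitly.
    """
    path = Path(path)
    df = pd.read_csv(path)
    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if fs is None:
        fs = meta.pop("fs", None)
        meta.pop("labels", None)
    if fs is None:
        raise ValueError(f"no sampling rate: {sidecar} missing and fs not given")
    return Recording(df.to_numpy().T, float(fs), tuple(df.columns), meta)
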