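"""Magnitude-squared coherence networks from Welch spectra.

For two channels ``X(t)``, ``Y(t)`` the magnitude-squared coherence at
frequency ``f`` is

    C_XY(f) = |P_XY(f)|^2 / (P_XX(f) * P_YY(f))

with ``P_XY`` the Welch cross-spectrum (averaged tapered, overlapped
periodograms) and ``P_XX``, ``P_YY`` the auto-spectra.  Band-averaging
``C_XY(f)`` over the analysis band gives one edge weight; all pairwise
edges over the montage form a symmetric adjacency matrix with unit
diagonal, the weighted functional network of one EEG segment.  Segment
matrices are then averaged into one network per subject/task.

All spectra for a segment are computed from a single batch of windowed
FFTs, so the full 21x21 matrix costs one FFT per channel per window; the
result is identical (to rounding) to per-pair ``scipy.signal.csd``.

A key estimator property: with ``M`` (effectively independent) Welch
windows, the coherence of two *independent* signals is biased upward by
about ``1/M``; a single window gives identically 1.  A minimum of two
windows is therefore enforced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import get_window

from .montage import CANONICAL_21

#: Default analysis band in Hz (broadband; recorded with every output).
DEFAULT_BAND: tuple[float, float] = (1.0, 45.0)


@dataclass(frozen=True)
class WelchParams:
    """Welch estimation settings: window length (s), overlap fraction, taper."""

    window: float = 1.0
    overlap: float = 0.5
    taper: str = "hann"

    def n_windows(self, n_samples: int, fs: float) -> int:
        nper = int(round(self.window * fs))
        step = max(1, int(round(nper * (1.0 - self.overlap))))
        if n_samples < nper:
            return 0
        return 1 + (n_samples - nper) // step


@dataclass
class SpectrumSet:
    """Auto- and cross-spectra of all channels on a common frequency grid.

    ``cross[i, j]`` is ``P_XiXj(f)`` (complex, Hermitian in ``i, j``);
    ``auto[i] == cross[i, i].real``.
    """

    freqs: np.ndarray
    auto: np.ndarray          # (n_channels, n_freqs), >= 0
    cross: np.ndarray         # (n_channels, n_channels, n_freqs), complex
    welch: WelchParams
    n_windows: int


@dataclass
class CoherenceMatrix:
    """Band-averaged coherence adjacency matrix of one network.

    Symmetric, unit diagonal, entries in [0, 1].
    """

    values: np.ndarray
    labels: tuple[str, ...]
    band: tuple[float, float]
    n_segments_averaged: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = tuple(self.labels)
        self.band = (float(self.band[0]), float(self.band[1]))
        validate_coherence_matrix(self.values, len(self.labels))

    @property
    def n(self) -> int:
        return len(self.labels)

    def edge(self, a: str, b: str) -> float:
        """Coherence between electrodes ``a`` and ``b``."""
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def validate_coherence_matrix(values: np.ndarray, n_labels: int) -> None:
    if values.shape != (n_labels, n_labels):
        raise ValueError(f"matrix shape {values.shape} != ({n_labels}, {n_labels})")
    if not np.allclose(values, values.T, atol=1e-10):
        raise ValueError("coherence matrix must be symmetric")
    if not np.allclose(np.diag(values), 1.0, atol=1e-10):
        raise ValueError("coherence matrix diagonal must be 1")
    if values.min() < -1e-12 or values.max() > 1 + 1e-12:
        raise ValueError("coherence values must lie in [0, 1]")


def welch_spectra(
    segment: np.ndarray,
    fs: float,
    welch: WelchParams = WelchParams(),
) -> SpectrumSet:
    """Welch auto/cross spectral densities for every channel pair.

    One-sided densities with the same scaling conventions as
    ``scipy.signal.welch``/``csd`` (constant detrend per window, taper
    power normalization, doubling of non-DC/Nyquist bins).
    """
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    n_ch, n_samp = segment.shape
    nper = int(round(welch.window * fs))
    if nper > n_samp:
        raise ValueError(
            f"Welch window of {nper} samples longer than segment ({n_samp})"
        )
    step = max(1, int(round(nper * (1.0 - welch.overlap))))
    starts = np.arange(0, n_samp - nper + 1, step)
    m = len(starts)
    if m < 2:
        raise ValueError(
            "need at least 2 Welch windows per segment: a single-window "
            "magnitude-squared coherence is identically 1"
        )
    win = get_window(welch.taper, nper)
    scale = 1.0 / (fs * (win**2).sum())

    # (m, n_ch, nper) windowed, detrended, tapered frames -> rFFT once
    frames = np.stack([segment[:, s : s + nper] for s in starts])
    frames = frames - frames.mean(axis=-1, keepdims=True)
    fft = np.fft.rfft(frames * win, axis=-1)

    # cross[i, j, f] = mean_m conj(fft[m, i, f]) * fft[m, j, f]  (scipy csd convention)
    cross = np.einsum("mif,mjf->ijf", fft.conj(), fft) * (scale / m)
    # one-sided density: double all bins except DC (and Nyquist when present)
    cross[..., 1:] *= 2.0
    if nper % 2 == 0:
        cross[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    auto = np.einsum("iif->if", cross).real.copy()
    return SpectrumSet(freqs=freqs, auto=auto, cross=cross, welch=welch, n_windows=m)


def coherence_spectrum(spec: SpectrumSet, i: int, j: int) -> np.ndarray:
    """``C(f) = |P_ij|^2 / (P_ii * P_jj)``; bins with zero power map to 0."""
    if i == j:
        raise ValueError("coherence requires two distinct channels")
    n_ch = spec.auto.shape[0]
    if not (0 <= i < n_ch and 0 <= j < n_ch):
        raise IndexError(f"channel index out of range for {n_ch} channels")
    denom = spec.auto[i] * spec.auto[j]
    num = np.abs(spec.cross[i, j]) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(c, 0.0, 1.0)


def band_average(
    cspec: np.ndarray, freqs: np.ndarray, band: tuple[float, float]
) -> float:
    """Unweighted mean of ``cspec`` over bins with ``lo <= f <= hi`` inclusive."""
    lo, hi = band
    if not lo < hi:
        raise ValueError("band must satisfy lo < hi")
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError(f"band {band} contains no frequency bins")
    return float(np.asarray(cspec)[mask].mean())


def coherence_matrix(
    segment: np.ndarray,
    fs: float,
    labels: tuple[str, ...] | list[str],
    band: tuple[float, float] = DEFAULT_BAND,
    welch: WelchParams = WelchParams(),
    segment_labels: tuple[str, ...] | list[str] | None = None,
) -> CoherenceMatrix:
    """All-pairs band-averaged coherence adjacency for one segment.

    ``labels`` selects and orders the network nodes; if ``segment_labels``
    is given, channels are matched by name and extra channels dropped.
    """
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    labels = tuple(labels)
    if segment_labels is not None:
        segment_labels = tuple(segment_labels)
        missing = [lab for lab in labels if lab not in segment_labels]
        if missing:
            raise KeyError(f"label(s) {missing} not present in segment channels")
        idx = [segment_labels.index(lab) for lab in labels]
        segment = segment[idx]
    elif segment.shape[0] != len(labels):
        raise ValueError(
            f"{segment.shape[0]} channels but {len(labels)} labels "
            "(pass segment_labels to select by name)"
        )

    spec = welch_spectra(segment, fs, welch)
    lo, hi = band
    mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not mask.any():
        raise ValueError(f"band {band} contains no frequency bins")
    denom = spec.auto[:, None, :] * spec.auto[None, :, :]
    num = np.abs(spec.cross) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    values = np.clip(c[:, :, mask].mean(axis=2), 0.0, 1.0)
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 1.0)
    return CoherenceMatrix(
        values=values,
        labels=labels,
        band=band,
        n_segments_averaged=1,
        meta={"welch": vars(welch) | {"n_windows": spec.n_windows}},
    )


def average_matrices(matrices: list[CoherenceMatrix]) -> CoherenceMatrix:
    """Element-wise mean of segment networks -> one subject/task network."""
    if not matrices:
        raise ValueError("cannot average an empty list of matrices")
    first = matrices[0]
    for m in matrices[1:]:
        if m.labels != first.labels:
            raise ValueError("label mismatch between coherence matrices")
        if m.band != first.band:
            raise ValueError("band mismatch between coherence matrices")
    total = sum(m.n_segments_averaged for m in matrices)
    stack = np.stack(
        [m.values * m.n_segments_averaged for m in matrices]
    )
    values = stack.sum(axis=0) / total
    np.fill_diagonal(values, 1.0)
    return CoherenceMatrix(
        values=values,
        labels=first.labels,
        band=first.band,
        n_segments_averaged=total,
        meta=dict(first.meta),
    )


def write_matrix(cm: CoherenceMatrix, path: str | Path) -> None:
    """CSV with label header/index + JSON sidecar (band, Welch, segments)."""
    path = Path(path)
    df = pd.DataFrame(cm.values, index=list(cm.labels), columns=list(cm.labels))
    df.to_csv(path, float_format="%.8f")
    sidecar = {
        "band": list(cm.band),
        "n_segments_averaged": cm.n_segments_averaged,
        **cm.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_matrix(path: str | Path) -> CoherenceMatrix:
    """Read a matrix written by :func:`write_matrix`; invariants re-validated."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    meta: dict = {}
    band = DEFAULT_BAND
    n_seg = 1
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        band = tuple(meta.pop("band", band))
        n_seg = int(meta.pop("n_segments_averaged", n_seg))
    values = df.to_numpy()
    values = 0.5 * (values + values.T)  # undo CSV rounding asymmetry
    return CoherenceMatrix(
        values=values,
        labels=tuple(df.columns),
        band=band,
        n_segments_averaged=n_seg,
        meta=meta,
    )


__all__ = [
    "CANONICAL_21",
    "DEFAULT_BAND",
    "WelchParams",
    "SpectrumSet",
    "CoherenceMatrix",
    "welch_spectra",
    "coherence_spectrum",
    "band_average",
    "coherence_matrix",
    "average_matrices",
    "write_matrix",
    "read_matrix",
]
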