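from __future__ import annotations

import numpy as np
import pytest

from cohnet.connectivity import CoherenceMatrix
from cohnet.recording import Recording
from cohnet.synthetic import SimConfig, inject_ocular_artifacts, simulate_recording

#: Scaled-down simulation settings used throughout the suite: same
#: montage, coupling, and artifact structure as the full study, shorter
#: recordings at a lower rate so the whole suite stays fast.
FAST_SIM = dict(fs=200.0, duration=12.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230427)


@pytest.fixture
def small_config() -> SimConfig:
    return SimConfig(n_sp=3, n_hc=3, seed=11, **FAST_SIM)


@pytest.fixture
def hc_recording(small_config) -> Recording:
    return simulate_recording(small_config, "hc", seed=5)


@pytest.fixture
def blink_recording() -> tuple[Recording, np.ndarray]:
    """A 40-s control recording with 150-uV blinks and ground-truth times."""
    cfg = SimConfig(n_sp=2, n_hc=2, fs=250.0, duration=40.0, seed=3)
    rec = simulate_recording(cfg, "hc", seed=42)
    return inject_ocular_artifacts(rec, rate=12.0, amplitude=150.0, seed=7)


def random_weighted_graph(
    rng: np.random.Generator, n: int, w_lo: float = 0.05, w_hi: float = 1.0
) -> np.ndarray:
    """Random complete symmetric weight matrix with zero diagonal."""
    w = rng.uniform(w_lo, w_hi, size=(n, n))
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    return w


def toy_matrix(values: np.ndarray, labels: tuple[str, ...]) -> CoherenceMatrix:
    v = np.asarray(values, dtype=float)
    np.fill_diagonal(v, 1.0)
    return CoherenceMatrix(values=v, labels=labels, band=(1.0, 45.0))
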