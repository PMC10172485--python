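"""Synthetic EEG cohort with planted coherence structure and clinical tables.

The generator emulates a two-group treatment study: a patient group
("SP", recorded before and after treatment) and healthy controls ("HC"),
each performing three executive tasks while EEG is recorded on the
21-electrode 10-20 montage.  Ground truth is fully controlled:

* Every channel is unit-variance "background cortex" noise (1/f spectrum
  plus an 8-12 Hz alpha bump) partly replaced by shared band-limited
  sources.  A global source gives all channel pairs a background
  coherence; a second source shared by a medial fronto-parietal node set
  (a default-mode-network proxy) raises coherence within that clique in
  the pre-treatment patient condition.
* Mixing uses an equal-power construction: with unit-variance sources
  ``s`` and per-channel noise ``n``, a channel is
  ``a_b*s_glob + a_e*s_dmn + sqrt(1 - a_b^2 - a_e^2) * n`` where
  ``a_b^2 = sqrt(C_bg)`` and ``a_b^2 + a_e^2 = sqrt(C_planted)`` for the
  *underlying* coherences ``C``.  Because every channel keeps unit
  power, edges between planted and background nodes keep exactly the
  background coherence — the planted effect is confined to the clique.
* Underlying coherence targets are numerically calibrated against the
  package's own Welch coherence estimator, so that the *measured*
  band-averaged coherence (which carries the finite-window estimator
  bias, about 1/M for M windows) hits the configured targets.
* Ocular (blink) artifacts are slow large-amplitude transients with a
  frontally dominated topography, injected at a Poisson rate with ground
  truth timestamps.
* The clinical table couples each patient's symptom improvement (PANSS
  change ratio) linearly to the treatment-induced change in the network
  characteristic path length, plus behavioral indicators (reaction
  times, errors, solution steps) with group/task shifts matching the
  study conditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import (
    DEFAULT_BAND,
    WelchParams,
    average_matrices,
    coherence_matrix,
)
from .montage import CANONICAL_21, DMN_PROXY_NODES, OCULAR_TOPOGRAPHY, dmn_proxy_edges
from .recording import Recording

_CONDITIONS = ("sp_before", "sp_after", "hc")

#: Group-level behavioral parameters per task and condition:
#: reaction-time (mean, sd) in seconds, modelled lognormal, and the count
#: indicator (Tower-of-Hanoi solution steps above the 7-move minimum, or
#: Trail-Making error counts), modelled Poisson.
BEHAVIOR_PARAMS: dict[str, dict[str, dict[str, tuple[float, float] | float]]] = {
    "THT": {
        "sp_before": {"rt": (90.71, 61.17), "count": 11.38},
        "sp_after": {"rt": (87.67, 61.27), "count": 12.38},
        "hc": {"rt": (66.42, 52.03), "count": 7.17},
    },
    "TMT-A": {
        "sp_before": {"rt": (63.57, 22.96), "count": 0.38},
        "sp_after": {"rt": (50.57, 18.93), "count": 0.45},
        "hc": {"rt": (35.29, 10.35), "count": 0.29},
    },
    "TMT-B": {
        "sp_before": {"rt": (203.00, 94.05), "count": 4.19},
        "sp_after": {"rt": (160.95, 56.72), "count": 2.00},
        "hc": {"rt": (82.33, 35.16), "count": 0.33},
    },
}

TASKS = ("THT", "TMT-A", "TMT-B")

#: PANSS total pre-treatment distribution (mean, sd) of the emulated cohort.
PANSS_PRE = (74.62, 13.76)
PANSS_RANGE = (30, 210)


@dataclass
class SimConfig:
    """All knobs of the synthetic study; ``seed`` fixes every byte."""

    n_sp: int = 21
    n_hc: int = 24
    fs: float = 1000.0
    duration: float = 60.0
    montage: tuple[str, ...] = CANONICAL_21
    dmn_edges: tuple[tuple[str, str], ...] = field(default_factory=dmn_proxy_edges)
    coupling_base: float = 0.3
    coupling_effect: float = 0.3
    global_effect: float = 0.0
    after_attenuation: float = 1.0
    effect_subject_sd: float = 0.0
    signal_scale: float = 20.0          # channel RMS amplitude, uV
    artifact_rate: float = 6.0          # blinks per minute
    artifact_amplitude: float = 150.0   # uV at the frontopolar sites
    panss_intercept: float = 0.197
    panss_slope: float = -2.081
    panss_noise_sd: float = 0.03
    band: tuple[float, float] = DEFAULT_BAND
    welch: WelchParams = field(default_factory=WelchParams)
    seg_len: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sp < 2 or self.n_hc < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if not 0.0 <= self.coupling_base <= 1.0:
            raise ValueError("coupling_base must be in [0, 1]")
        if not (
            0.0
            <= self.coupling_base + self.global_effect + self.coupling_effect
            <= 1.0
        ):
            raise ValueError(
                "coupling_base + global_effect + coupling_effect must be in [0, 1]"
            )
        self.montage = tuple(self.montage)
        self.dmn_edges = tuple(tuple(e) for e in self.dmn_edges)
        for a, b in self.dmn_edges:
            if a == b or a not in self.montage or b not in self.montage:
                raise ValueError(f"invalid planted edge ({a}, {b})")

    @property
    def dmn_nodes(self) -> tuple[str, ...]:
        """Union of the planted-edge endpoints (the planted clique)."""
        nodes = []
        for a, b in self.dmn_edges:
            for lab in (a, b):
                if lab not in nodes:
                    nodes.append(lab)
        return tuple(nodes)


@dataclass
class CohortBundle:
    """A complete simulated study: recordings, clinical table, ground truth."""

    recordings: dict[tuple[str, str, str], Recording]
    clinical: pd.DataFrame
    artifact_times: dict[tuple[str, str, str], np.ndarray]
    config: SimConfig
    truth: dict

    def subjects(self, group: str) -> list[str]:
        return sorted(self.clinical.loc[self.clinical.group == group, "subject"].unique())


# ---------------------------------------------------------------------------
# spectral shaping and coherence calibration
# ---------------------------------------------------------------------------

def _shaped_noise(n_series: int, n_samples: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance series with a 1/f amplitude spectrum plus an alpha bump.

    All sources and channel noises share this spectral shape, which makes
    the pairwise coherence flat across frequency (band choice then cannot
    shift the planted targets).
    """
    n_f = n_samples // 2 + 1
    f = np.fft.rfftfreq(n_samples, 1.0 / fs)
    amp = np.zeros(n_f)
    amp[1:] = 1.0 / np.sqrt(f[1:])
    amp += 2.0 * np.exp(-0.5 * ((f - 10.0) / 1.5) ** 2)
    spec = amp * (
        rng.standard_normal((n_series, n_f)) + 1j * rng.standard_normal((n_series, n_f))
    )
    spec[:, 0] = 0.0
    x = np.fft.irfft(spec, n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


_CALIBRATION_SEED = 813_229_111
_calibration_cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _calibration_curve(
    seg_len: float,
    fs: float,
    welch: WelchParams,
    band: tuple[float, float],
    n_segments: int = 60,
) -> tuple[np.ndarray, np.ndarray]:
    """Measured band coherence as a function of underlying coherence.

    Simulates two unit-variance channels sharing a source at a grid of
    underlying coherences and measures the band-averaged Welch coherence
    with the package's own estimator; returns the monotone (underlying,
    measured) grid used for inversion.  Deterministic: fixed internal seed.
    """
    key = (round(seg_len, 6), round(welch.window, 6), round(welch.overlap, 6),
           welch.taper, tuple(round(b, 6) for b in band), int(n_segments))
    if key in _calibration_cache:
        return _calibration_cache[key]
    rng = np.random.default_rng(_CALIBRATION_SEED)
    # calibrate at a small internal rate: the estimator's bias depends on
    # windows-per-segment and band shape, not on the absolute rate
    cal_fs = 256.0
    n_samp = int(round(seg_len * cal_fs))
    grid = np.concatenate([[0.0], np.linspace(0.02, 0.98, 25)])
    measured = np.empty_like(grid)
    for gi, c_underlying in enumerate(grid):
        a2 = np.sqrt(c_underlying)          # shared-source power fraction
        a = np.sqrt(a2)
        b_noise = np.sqrt(max(0.0, 1.0 - a2))
        vals = np.empty(n_segments)
        for s in range(n_segments):
            src = _shaped_noise(3, n_samp, cal_fs, rng)
            x = a * src[0] + b_noise * src[1]
            y = a * src[0] + b_noise * src[2]
            cm = coherence_matrix(
                np.vstack([x, y]), cal_fs, ("FP1", "FP2"), band=band, welch=welch
            )
            vals[s] = cm.values[0, 1]
        measured[gi] = vals.mean()
    measured = np.maximum.accumulate(measured)  # enforce monotone map
    _calibration_cache[key] = (grid, measured)
    return grid, measured


def calibrate_underlying(
    target: float,
    seg_len: float = 3.0,
    fs: float = 1000.0,
    welch: WelchParams = WelchParams(),
    band: tuple[float, float] = DEFAULT_BAND,
) -> float:
    """Underlying coherence whose *measured* band coherence equals ``target``.

    Targets at or below the estimator's independence bias floor map to 0
    (no shared source can produce a measured coherence below the floor).
    """
    if not 0.0 <= target <= 1.0:
        raise ValueError("coherence target must be in [0, 1]")
    grid, measured = _calibration_curve(seg_len, fs, welch, band)
    if target <= measured[0]:
        return 0.0
    return float(np.interp(target, measured, grid))


# ---------------------------------------------------------------------------
# recording simulation
# ---------------------------------------------------------------------------

def simulate_recording(
    config: SimConfig,
    condition: str,
    seed: int,
    effect: float | None = None,
    global_effect: float | None = None,
) -> Recording:
    """One multichannel recording under ``condition``.

    ``condition`` is ``sp_before`` (full planted and global effects),
    ``sp_after`` (effects attenuated by ``config.after_attenuation``) or
    ``hc`` (background only).  ``effect`` overrides
    ``config.coupling_effect`` (used for per-subject heterogeneity).

    The shared sources enter with alternating-sign mixing patterns
    (sign has no effect on magnitude-squared coherence): the mixed
    component is then nearly orthogonal to the common mode, so the
    planted structure survives average re-referencing instead of being
    subtracted out with the reference.
    """
    if condition not in _CONDITIONS:
        raise ValueError(f"condition must be one of {_CONDITIONS}")
    eff = config.coupling_effect if effect is None else effect
    glob = config.global_effect if global_effect is None else global_effect
    if condition == "hc":
        eff = 0.0
        glob = 0.0
    elif condition == "sp_after":
        eff = eff * (1.0 - config.after_attenuation)
        glob = glob * (1.0 - config.after_attenuation)
    base_t = config.coupling_base + glob
    planted_t = base_t + eff
    if not 0.0 <= planted_t <= 1.0:
        raise ValueError("planted coherence target outside [0, 1]")

    c_bg = calibrate_underlying(base_t, config.seg_len, config.fs, config.welch, config.band)
    c_pp = calibrate_underlying(planted_t, config.seg_len, config.fs, config.welch, config.band)
    a_b2 = np.sqrt(c_bg)                 # background-source power fraction
    tot2 = max(np.sqrt(c_pp), a_b2)      # planted-channel shared power fraction
    a_e2 = tot2 - a_b2

    rng = np.random.default_rng(seed)
    n_ch = len(config.montage)
    n_samp = int(round(config.duration * config.fs))
    series = _shaped_noise(n_ch + 2, n_samp, config.fs, rng)
    s_glob, s_dmn, noise = series[0], series[1], series[2:]

    # alternating signs in montage order; the clique source reuses each
    # node's background sign so the two shared components always add
    # constructively within planted pairs
    signs = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(n_ch)])
    planted = set(config.dmn_nodes)
    data = np.empty((n_ch, n_samp))
    for i, lab in enumerate(config.montage):
        shared2 = tot2 if lab in planted else a_b2
        a_e = np.sqrt(a_e2) if lab in planted else 0.0
        data[i] = signs[i] * (np.sqrt(a_b2) * s_glob + a_e * s_dmn) + np.sqrt(
            max(0.0, 1.0 - shared2)
        ) * noise[i]
    data *= config.signal_scale
    return Recording(
        data, config.fs, config.montage,
        meta={"condition": condition, "seed": int(seed)},
    )


_BLINK_WIDTH_S = 0.35  # half-cosine-squared bell; spectral content < 4 Hz


def inject_ocular_artifacts(
    rec: Recording,
    rate: float,
    amplitude: float,
    seed: int,
) -> tuple[Recording, np.ndarray]:
    """Add blink-like transients; returns (noisy recording, event times in s).

    The event count is Poisson with mean ``rate * duration / 60``; each
    event is a ~0.35 s raised-cosine deflection with the frontal-dominant
    topography of ocular artifacts (largest at FP1/FP2/FPz).
    """
    if rate < 0 or amplitude < 0:
        raise ValueError("rate and amplitude must be nonnegative")
    if rate == 0 or amplitude == 0:
        return rec.copy_with(rec.data.copy()), np.empty(0)
    rng = np.random.default_rng(seed)
    n_events = rng.poisson(rate * rec.duration / 60.0)
    width = int(round(_BLINK_WIDTH_S * rec.fs))
    if n_events == 0 or rec.n_samples <= width:
        return rec.copy_with(rec.data.copy()), np.empty(0)
    starts = np.sort(rng.integers(0, rec.n_samples - width, size=n_events))
    bell = amplitude * np.sin(np.pi * np.arange(width) / width) ** 2
    topo = np.array([OCULAR_TOPOGRAPHY.get(lab, 0.05) for lab in rec.labels])
    data = rec.data.copy()
    for s0 in starts:
        data[:, s0 : s0 + width] += np.outer(topo, bell)
    times = (starts + width / 2) / rec.fs
    return rec.copy_with(data), times


# ---------------------------------------------------------------------------
# clinical simulation
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def simulate_clinical(
    config: SimConfig,
    delta_l: np.ndarray,
    seed: int,
) -> pd.DataFrame:
    """Per-subject clinical/behavioral table.

    ``delta_l`` gives each SP subject's treatment-induced change in
    characteristic path length; the latent PANSS change ratio is
    ``a + b * delta_l + eps`` (``eps ~ N(0, panss_noise_sd)``), clipped to
    [0, 1).  Post-treatment scores are ``pre * (1 - ratio)`` rounded
    half-even and clipped to the 30-210 scale; the realized change ratio
    is recomputed from the rounded scores.

    Behavioral indicators per task: reaction time (lognormal) and a count
    (Poisson) — Tower-of-Hanoi solution steps (7-move floor for 3 disks)
    or Trail-Making error counts — with group/task level parameters from
    the emulated study conditions.
    """
    delta_l = np.asarray(delta_l, dtype=float)
    if len(delta_l) != config.n_sp:
        raise ValueError(
            f"need one delta_l per SP subject ({config.n_sp}), got {len(delta_l)}"
        )
    rng = np.random.default_rng(seed)
    rows = []

    def behavior(cond: str) -> dict[str, float]:
        out: dict[str, float] = {}
        for task in TASKS:
            p = BEHAVIOR_PARAMS[task][cond]
            mu, sig = _lognormal_params(*p["rt"])  # type: ignore[misc]
            out[f"rt_{task}"] = float(rng.lognormal(mu, sig))
            count = int(rng.poisson(p["count"]))
            if task == "THT":
                out[f"steps_{task}"] = 7 + count
            else:
                out[f"errors_{task}"] = count
        return out

    pre_mu, pre_sd = PANSS_PRE
    for i in range(config.n_sp):
        sid = f"sp{i:03d}"
        pre = float(np.clip(np.round(rng.normal(pre_mu, pre_sd)), *PANSS_RANGE))
        latent = config.panss_intercept + config.panss_slope * delta_l[i]
        latent += rng.normal(0.0, config.panss_noise_sd) if config.panss_noise_sd > 0 else 0.0
        latent = float(np.clip(latent, 0.0, 1.0 - 1e-9))
        post = float(np.clip(np.round(pre * (1.0 - latent)), *PANSS_RANGE))
        realized = (pre - post) / pre
        for phase, cond in (("before", "sp_before"), ("after", "sp_after")):
            rows.append({
                "subject": sid, "group": "SP", "phase": phase,
                "panss_pre": pre, "panss_post": post,
                "change_ratio_model": latent, "change_ratio": realized,
                "delta_l": delta_l[i],
                **behavior(cond),
            })
    for i in range(config.n_hc):
        sid = f"hc{i:03d}"
        rows.append({
            "subject": sid, "group": "HC", "phase": "before",
            "panss_pre": np.nan, "panss_post": np.nan,
            "change_ratio_model": np.nan, "change_ratio": np.nan,
            "delta_l": np.nan,
            **behavior("hc"),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole-cohort assembly
# ---------------------------------------------------------------------------

def _subject_network_l(
    rec: Recording, config: SimConfig
) -> float:
    """Characteristic path length of a clean recording (truth pipeline)."""
    from .graph import network_properties
    from .preprocess import segment

    segs = segment(rec, config.seg_len)
    mats = [
        coherence_matrix(s, config.fs, config.montage, config.band, config.welch)
        for s in segs.segments
    ]
    return network_properties(average_matrices(mats)).path_length


def simulate_cohort(
    config: SimConfig,
    network_coupled_outcome: bool = True,
) -> CohortBundle:
    """Generate the full study: recordings (with artifacts), clinical, truth.

    SP subjects are recorded in both phases of every task; HC subjects
    once.  When ``network_coupled_outcome`` is true the PANSS change
    ratio is coupled to each SP subject's *realized* change in
    characteristic path length, computed from the clean (pre-artifact)
    recordings with the package's own connectivity and graph modules;
    otherwise latent per-subject effect sizes stand in.
    """
    root = np.random.SeedSequence(config.seed)
    seeds = root.spawn(4)
    rec_rng = np.random.default_rng(seeds[0])
    art_rng = np.random.default_rng(seeds[1])
    het_rng = np.random.default_rng(seeds[2])

    recordings: dict[tuple[str, str, str], Recording] = {}
    artifact_times: dict[tuple[str, str, str], np.ndarray] = {}
    # per-subject treatment-effect multiplier scales both the clique and
    # the global component of the pre-treatment hyperconnectivity
    mult = np.ones(config.n_sp)
    if config.effect_subject_sd > 0:
        mult = np.clip(
            1.0 + het_rng.normal(0.0, config.effect_subject_sd, config.n_sp), 0.0, None
        )
    head = 1.0 - config.coupling_base
    effects = np.clip(config.coupling_effect * mult, 0.0, head)
    globals_ = np.clip(config.global_effect * mult, 0.0, head - effects)

    delta_l = np.zeros(config.n_sp)
    sp_ids = [f"sp{i:03d}" for i in range(config.n_sp)]
    hc_ids = [f"hc{i:03d}" for i in range(config.n_hc)]

    def _store(key: tuple[str, str, str], rec: Recording) -> None:
        noisy, times = inject_ocular_artifacts(
            rec,
            config.artifact_rate,
            config.artifact_amplitude,
            int(art_rng.integers(2**31)),
        )
        recordings[key] = noisy
        artifact_times[key] = times

    for i, sid in enumerate(sp_ids):
        l_before, l_after = [], []
        for task in TASKS:
            before = simulate_recording(
                config, "sp_before", int(rec_rng.integers(2**31)),
                effect=float(effects[i]), global_effect=float(globals_[i]),
            )
            after = simulate_recording(
                config, "sp_after", int(rec_rng.integers(2**31)),
                effect=float(effects[i]), global_effect=float(globals_[i]),
            )
            if network_coupled_outcome:
                l_before.append(_subject_network_l(before, config))
                l_after.append(_subject_network_l(after, config))
            _store((sid, task, "before"), before)
            _store((sid, task, "after"), after)
        if network_coupled_outcome:
            delta_l[i] = float(np.mean(l_after) - np.mean(l_before))

    for sid in hc_ids:
        for task in TASKS:
            rec = simulate_recording(config, "hc", int(rec_rng.integers(2**31)))
            _store((sid, task, "before"), rec)

    clinical = simulate_clinical(
        config, delta_l, int(seeds[3].generate_state(1)[0] % 2**31)
    )
    truth = {
        "config": _config_dict(config),
        "subject_effects": {sid: float(e) for sid, e in zip(sp_ids, effects)},
        "delta_l": {sid: float(d) for sid, d in zip(sp_ids, delta_l)},
        "network_coupled_outcome": network_coupled_outcome,
    }
    return CohortBundle(recordings, clinical, artifact_times, config, truth)


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["welch"] = vars(config.welch)
    return d


def write_cohort(bundle: CohortBundle, out_dir: str | Path) -> None:
    """Persist a cohort: recordings as CSV+sidecar, clinical CSV, truth JSON."""
    from .recording import write_recording

    out = Path(out_dir)
    rec_dir = out / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    for (sid, task, phase), rec in bundle.recordings.items():
        write_recording(rec, rec_dir / f"{sid}_{task}_{phase}.csv")
    bundle.clinical.to_csv(out / "clinical.csv", index=False)
    truth = dict(bundle.truth)
    truth["artifact_times"] = {
        "_".join(k): v.tolist() for k, v in bundle.artifact_times.items()
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))


__all__ = [
    "SimConfig",
    "CohortBundle",
    "BEHAVIOR_PARAMS",
    "TASKS",
    "simulate_recording",
    "inject_ocular_artifacts",
    "simulate_clinical",
    "simulate_cohort",
    "write_cohort",
    "calibrate_underlying",
]
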