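"""Ground-truth properties of the synthetic cohort generator."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.stats import spearmanr

from cohnet.connectivity import average_matrices, coherence_matrix
from cohnet.preprocess import reject_segments, segment
from cohnet.synthetic import (
    SimConfig,
    calibrate_underlying,
    inject_ocular_artifacts,
    simulate_clinical,
    simulate_cohort,
    simulate_recording,
)

from conftest import FAST_SIM


def mean_matrix(cfg: SimConfig, condition: str, seed: int) -> np.ndarray:
    rec = simulate_recording(cfg, condition, seed)
    segs = segment(rec, cfg.seg_len)
    mats = [
        coherence_matrix(s, cfg.fs, cfg.montage, cfg.band, cfg.welch)
        for s in segs.segments
    ]
    return average_matrices(mats).values


def edge_means(cfg: SimConfig, values: np.ndarray) -> tuple[float, float]:
    """(planted-edge mean, background-edge mean) of one adjacency matrix."""
    lab = cfg.montage
    planted = set(cfg.dmn_nodes)
    p_idx = [
        (lab.index(a), lab.index(b))
        for a, b in itertools.combinations(sorted(planted), 2)
    ]
    b_idx = [
        (i, j)
        for i in range(len(lab))
        for j in range(i + 1, len(lab))
        if not (lab[i] in planted and lab[j] in planted)
    ]
    p = float(np.mean([values[i, j] for i, j in p_idx]))
    b = float(np.mean([values[i, j] for i, j in b_idx]))
    return p, b


class TestPlantedCoherence:
    def test_no_effect_no_gap(self):
        cfg = SimConfig(n_sp=2, n_hc=2, coupling_effect=0.0, seed=0, **FAST_SIM)
        gaps = []
        for s in range(8):
            p, b = edge_means(cfg, mean_matrix(cfg, "sp_before", 50 + s))
            gaps.append(p - b)
        assert abs(np.mean(gaps)) < 0.03

    def test_zero_base_hits_welch_bias_floor(self):
        # all channels independent -> measured coherence ~ 1/M (M=5 windows)
        cfg = SimConfig(n_sp=2, n_hc=2, coupling_base=0.0, coupling_effect=0.0,
                        seed=0, **FAST_SIM)
        vals = []
        for s in range(8):
            m = mean_matrix(cfg, "hc", 70 + s)
            iu = np.triu_indices(len(cfg.montage), k=1)
            vals.append(m[iu].mean())
        assert np.mean(vals) == pytest.approx(1.0 / 5.0, abs=0.03)

    def test_effect_calibration_within_tolerance(self):
        # measured planted-minus-background gap ~ coupling_effect (0.3 +- 0.05)
        cfg = SimConfig(n_sp=2, n_hc=2, coupling_base=0.3, coupling_effect=0.3,
                        seed=0, **FAST_SIM)
        gaps = []
        for s in range(12):
            p, b = edge_means(cfg, mean_matrix(cfg, "sp_before", 100 + s))
            gaps.append(p - b)
        assert np.mean(gaps) == pytest.approx(0.3, abs=0.05)

    def test_hc_and_attenuated_after_have_no_gap(self):
        cfg = SimConfig(n_sp=2, n_hc=2, coupling_base=0.3, coupling_effect=0.3,
                        seed=0, **FAST_SIM)
        for cond in ("hc", "sp_after"):
            gaps = [
                np.subtract(*edge_means(cfg, mean_matrix(cfg, cond, 130 + s)))
                for s in range(6)
            ]
            assert abs(np.mean(gaps)) < 0.03

    def test_gap_monotone_in_effect(self):
        # larger planted effect => larger measured gap (Spearman rho > 0.9)
        effects = [0.0, 0.1, 0.2, 0.3, 0.4]
        eff_col, gap_col = [], []
        for e in effects:
            cfg = SimConfig(n_sp=2, n_hc=2, coupling_base=0.3, coupling_effect=e,
                            seed=0, **FAST_SIM)
            for s in range(10):
                p, b = edge_means(cfg, mean_matrix(cfg, "sp_before", 200 + s))
                eff_col.append(e)
                gap_col.append(p - b)
        rho = spearmanr(eff_col, gap_col).statistic
        assert rho > 0.9

    def test_invalid_condition_rejected(self, small_config):
        with pytest.raises(ValueError, match="condition"):
            simulate_recording(small_config, "patient", 0)

    def test_target_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(coupling_base=0.8, coupling_effect=0.4)

    def test_calibration_maps_zero_to_zero(self):
        assert calibrate_underlying(0.0) == 0.0
        assert calibrate_underlying(0.1) == 0.0  # below the bias floor


class TestOcularInjection:
    def test_zero_rate_identity(self, hc_recording):
        out, times = inject_ocular_artifacts(hc_recording, 0.0, 150.0, seed=1)
        assert np.array_equal(out.data, hc_recording.data)
        assert len(times) == 0

    def test_event_count_poisson(self, small_config):
        rec = simulate_recording(
            SimConfig(n_sp=2, n_hc=2, fs=100.0, duration=60.0, seed=0), "hc", 3
        )
        counts = [
            len(inject_ocular_artifacts(rec, 12.0, 150.0, seed=s)[1])
            for s in range(200)
        ]
        assert np.mean(counts) == pytest.approx(12.0, abs=1.0)
        assert np.var(counts) == pytest.approx(12.0, rel=0.4)

    def test_frontal_dominance(self, hc_recording):
        out, times = inject_ocular_artifacts(hc_recording, 30.0, 200.0, seed=2)
        assert len(times) > 0
        delta = out.data - hc_recording.data
        fp1 = np.abs(delta[out.labels.index("FP1")]).max()
        o1 = np.abs(delta[out.labels.index("O1")]).max()
        assert fp1 > 5 * o1

    def test_large_blinks_trigger_segment_rejection(self, hc_recording):
        noisy, times = inject_ocular_artifacts(hc_recording, 20.0, 150.0, seed=3)
        assert len(times) > 0
        survived = reject_segments(segment(noisy, 3.0), 120.0)
        assert survived.rejected_count >= 1


class TestClinical:
    def test_noiseless_latent_ratio_exact(self):
        cfg = SimConfig(n_sp=3, n_hc=2, panss_intercept=0.2, panss_slope=-2.0,
                        panss_noise_sd=0.0, seed=0, **FAST_SIM)
        table = simulate_clinical(cfg, np.zeros(3), seed=1)
        sp = table[table.group == "SP"]
        assert np.allclose(sp.change_ratio_model, 0.2)

    def test_realized_ratio_consistent_with_scores(self):
        cfg = SimConfig(n_sp=5, n_hc=2, seed=0, **FAST_SIM)
        table = simulate_clinical(cfg, np.full(5, -0.02), seed=2)
        sp = table[table.group == "SP"].drop_duplicates("subject")
        assert np.allclose(
            sp.change_ratio, (sp.panss_pre - sp.panss_post) / sp.panss_pre
        )
        assert (sp.panss_pre >= 30).all() and (sp.panss_post >= 30).all()

    def test_behavior_directions_match_study_pattern(self):
        # patients slower than controls on the trail-making tasks;
        # Tower-of-Hanoi steps never below the 7-move minimum
        cfg = SimConfig(n_sp=40, n_hc=40, seed=0, **FAST_SIM)
        table = simulate_clinical(cfg, np.zeros(40), seed=3)
        before = table[(table.group == "SP") & (table.phase == "before")]
        hc = table[table.group == "HC"]
        assert before["rt_TMT-A"].mean() > hc["rt_TMT-A"].mean()
        assert before["rt_TMT-B"].mean() > hc["rt_TMT-B"].mean()
        assert before["errors_TMT-B"].mean() > hc["errors_TMT-B"].mean()
        assert (table["steps_THT"] >= 7).all()

    def test_length_mismatch_rejected(self):
        cfg = SimConfig(n_sp=3, n_hc=2, seed=0, **FAST_SIM)
        with pytest.raises(ValueError, match="delta_l"):
            simulate_clinical(cfg, np.zeros(2), seed=0)

    def test_slope_recoverable_from_noisy_ratios(self):
        # refitting the linear coupling recovers the slope (median over sims)
        from cohnet.prediction import fit_linear

        cfg = SimConfig(n_sp=21, n_hc=2, panss_noise_sd=0.03, seed=0, **FAST_SIM)
        rng = np.random.default_rng(5)
        slopes = []
        for s in range(200):
            delta_l = rng.normal(-0.02, 0.01, cfg.n_sp)
            table = simulate_clinical(cfg, delta_l, seed=1000 + s)
            sp = table[table.group == "SP"].drop_duplicates("subject")
            _, coefs = fit_linear(sp.delta_l.to_numpy()[:, None],
                                  sp.change_ratio.to_numpy())
            slopes.append(coefs[0])
        assert abs(np.median(slopes) - cfg.panss_slope) < 0.5


class TestCohortDeterminism:
    def test_same_seed_same_bytes(self):
        cfg = SimConfig(n_sp=2, n_hc=2, duration=6.0, fs=200.0, seed=9)
        b1 = simulate_cohort(cfg, network_coupled_outcome=False)
        b2 = simulate_cohort(cfg, network_coupled_outcome=False)
        assert b1.recordings.keys() == b2.recordings.keys()
        for k in b1.recordings:
            assert np.array_equal(b1.recordings[k].data, b2.recordings[k].data)
            assert np.array_equal(b1.artifact_times[k], b2.artifact_times[k])
        assert b1.clinical.equals(b2.clinical)

    def test_phase_structure(self):
        cfg = SimConfig(n_sp=2, n_hc=3, duration=6.0, fs=200.0, seed=9,
                        artifact_rate=0.0)
        bundle = simulate_cohort(cfg, network_coupled_outcome=False)
        sp_phases = {k[2] for k in bundle.recordings if k[0].startswith("sp")}
        hc_phases = {k[2] for k in bundle.recordings if k[0].startswith("hc")}
        assert sp_phases == {"before", "after"}
        assert hc_phases == {"before"}
        assert set(bundle.clinical.subject) == {
            k[0] for k in bundle.recordings
        }
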