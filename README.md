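# cohnet

Coherence-based EEG functional networks: from multichannel recordings
through preprocessing and weighted graph metrics to group statistics and
cross-validated prediction of clinical improvement.

## What this package is for

A recurring design in clinical EEG research compares patients before and
after treatment against healthy controls: record multichannel EEG during
cognitive tasks, estimate a functional-connectivity network per subject,
summarize each network with a few graph-theoretic scalars, test
group differences edge-by-edge and metric-by-metric, and finally ask
whether the *change* in network organization across treatment predicts
the change in clinical symptoms. `cohnet` implements that entire chain
as a tested, reusable library plus command-line pipeline, and — because
patient EEG is rarely shareable — ships a synthetic-cohort generator
with fully controlled ground truth so every stage can be validated.

The emulated study design: schizophrenia patients (n = 21, recorded
before and after 8 weeks of antipsychotic treatment) and healthy
controls (n = 24) performing three "cool" executive tasks (Tower of
Hanoi, Trail-Making A and B) while 21-channel 10–20 EEG is recorded at
1000 Hz. The clinical outcome is the PANSS change ratio
`(pre − post) / pre` of the 30-item Positive and Negative Syndrome
Scale.

## The method

**Connectivity.** For each artifact-free 3-s segment, every electrode
pair (X, Y) gets the magnitude-squared coherence

&nbsp;&nbsp;&nbsp;&nbsp;C_XY(f) = |P_XY(f)|² / (P_XX(f) · P_YY(f)),

with Welch auto-/cross-spectra P (1-s Hann windows, 50% overlap, M = 5
windows per segment), averaged over the analysis band (1–45 Hz by
default) and over segments, giving one 21×21 weighted adjacency matrix
per subject and task. With M windows the coherence of *independent*
signals is biased upward by ≈ 1/M; a minimum of two windows is enforced
(a single-window estimate is identically 1).

**Network metrics.** On the fully weighted graph (no thresholding; edge
length 1/w so strong coupling = short path), four standard weighted
measures in their Brain Connectivity Toolbox forms:

- `CLU` — mean Onnela clustering, Σ(ŵ_ij ŵ_ih ŵ_jh)^⅓ / k(k−1) with
  weights normalized by the graph maximum;
- `LE`  — mean local efficiency over neighborhood subgraphs;
- `GE`  — global efficiency, mean of 1/d_ij;
- `L`   — characteristic path length, mean of d_ij.

All four are verified against independent brute-force oracles
(Floyd–Warshall, exhaustive triple loops) to 1e−10.

**Preprocessing.** Zero-phase 0.1–45 Hz Butterworth filtering, common
average reference, FastICA decomposition with ocular components flagged
by an EOG-proxy correlation (|r| > 0.7 with the frontopolar average) or
excess kurtosis > 10, discrete-wavelet (db4) suppression of the large
coefficients inside flagged components (K = √(2 ln N) ·
median(|w|)/0.6745 per level), 3-s segmentation, and rejection of
segments exceeding ±120 µV.

**Statistics.** Shapiro–Wilk-gated test selection (pooled/Welch t by a
variance-ratio F gate, Mann–Whitney U or Wilcoxon signed-rank
otherwise), edge-wise two-sample t-tests with Benjamini–Hochberg FDR
over the 210 unique edges, and Pearson correlations with FDR.

**Prediction.** Per-patient changes ΔCLU, ΔLE, ΔGE, ΔL (after − before,
averaged over tasks) enter a multiple linear regression with
collinearity screening (VIF < 10, tolerance > 0.1), evaluated by
leave-one-out cross-validation: Pearson r between predicted and actual
change ratios, and RMSE in percentage points.

## Worked example

The shipped demo simulates a scaled-down study (8 patients, 8 controls,
24-s recordings at 200 Hz) in which the pre-treatment group carries
broad coherence hyperconnectivity (+0.30 on every edge) plus an extra
increment on a medial fronto-parietal clique, fully removed by
treatment, with 30% between-subject variation in treatment effect
driving the symptom coupling:

```python
import json, pandas as pd
from cohnet.experiments import behavioral_t_statistics
from cohnet.pipeline import demo_config, run_pipeline

for k, v in behavioral_t_statistics().items():
    print(f"{k}: {v:.2f}")

out = run_pipeline(demo_config(seed=0))
metrics = pd.read_csv(out / "metrics.csv")
print(metrics.groupby(["group", "phase"])[["clu", "le", "ge", "path_length"]]
      .mean().round(3))
report = json.loads((out / "prediction.json").read_text())
print("full model: ", report["formula"])
print(f"LOOCV r = {report['loocv_r']:.2f}, RMSE = {report['rmse_percent']:.2f}%")
```

prints

```
tht_rt_pooled_t: 1.44
tmt_a_rt_welch_t: 5.20
tmt_b_rt_welch_t: 5.55
                clu     le     ge  path_length
group phase
HC    before  0.858  0.313  0.313        3.215
SP    after   0.852  0.309  0.310        3.248
      before  0.894  0.651  0.651        1.592
full model:  y = 0.636 + 2.866*delta_clu - 1767.380*delta_le + 1767.653*delta_ge - 0.387*delta_l
LOOCV r = 0.93, RMSE = 2.33%
```

Reading the numbers: the behavioral t statistics are the
patient-vs-control reaction-time contrasts recomputed from the group
summary tables (pooled t for Tower of Hanoi, Welch t for the two
Trail-Making tasks). The metric table shows the expected pattern —
pre-treatment patients have higher clustering and efficiency and much
shorter characteristic paths than controls, and the post-treatment
phase returns to control levels. The prediction block regresses each
patient's symptom change ratio on their four network-change features;
at n = 8 the ΔLE/ΔGE features are nearly collinear (the huge paired
coefficients cancel — the VIF screen in the report flags them), and the
cross-validated correlation is unstable across seeds at this demo size.

The same stages are available as a CLI:

```bash
cohnet run-all --seed 0 --out results/demo
cohnet simulate --seed 1 --out cohort/
cohnet compare cohort_a/ cohort_b/ --out edges.csv
```

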