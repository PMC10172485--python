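# Methods

This note documents the models, estimators, parameter choices, and
numerical decisions behind `cohnet`, and what the synthetic validation
does and does not establish about real EEG.

## Coherence estimation

The connectivity measure is magnitude-squared coherence,
`C(f) = |P_XY|² / (P_XX P_YY)`, from Welch spectra computed per 3-s
segment. Defaults: 1-s Hann windows, 50% overlap (five windows per
segment), constant detrend per window, one-sided density scaling
identical to `scipy.signal.welch`/`csd` (the implementation batches all
channels through one FFT per window and is tested for exact agreement
with per-pair scipy calls). Band-averaging uses the unweighted mean
over bins with `lo ≤ f ≤ hi` inclusive; the default band is 1–45 Hz
broadband and is recorded in every output.

Two estimator properties matter downstream:

- **Independence bias.** With M (effectively independent) windows the
  expected coherence of independent Gaussian signals is ≈ 1/M. With
  the default five 50%-overlapped Hann windows the measured null mean
  is 0.207, close to the 1/M = 0.2 of five independent windows (Hann
  tapering nearly decorrelates half-overlapped windows). A minimum of
  two windows is enforced: single-window magnitude-squared coherence is
  identically 1.
- **Segment-then-average.** Coherence is estimated per segment and the
  adjacency matrices averaged, not pooled into one long estimate; with
  per-segment estimates the bias floor is constant across subjects and
  cancels in group contrasts.

## Synthetic cohort

Each channel is unit-variance background noise with a 1/f amplitude
spectrum plus an 8–12 Hz alpha bump. Shared structure is planted by
mixing common band-limited sources into the channels:

- a *background* source mixed into every channel (pairwise coherence
  `coupling_base`, default 0.3);
- a *clique* source mixed into a medial fronto-parietal node set
  {FPz, Fz, Cz, Pz, P3, P4} (all 15 pairs get
  `coupling_base + coupling_effect`, default +0.3, in the pre-treatment
  patient condition; healthy controls never have it; the post-treatment
  condition attenuates it by `after_attenuation`, default 100%);
- optionally a *global* treatment effect (`global_effect`) that raises
  the background coherence of every edge in the pre-treatment
  condition. The default is 0 (clique-only, used by the
  operating-characteristic experiments); the shipped demo uses 0.30
  (see "Demo study" below).

Three construction details:

1. **Equal-power mixing.** With unit-variance sources and noise, a
   channel is `a_b·s_bg + a_e·s_clique + √(1 − a_b² − a_e²)·n`, with
   `a_b² = √C_bg` and `a_b² + a_e² = √C_clique` for the underlying
   coherences. Every channel keeps unit power, so edges between
   planted and background nodes keep exactly the background coherence:
   the planted effect is confined to the clique, which is what makes
   false-positive accounting in the edge-wise tests meaningful.
2. **Signed mixing patterns.** Sources enter with alternating-sign
   gains across the montage (the clique source reuses each node's
   sign so the two components add constructively within the clique).
   Magnitude-squared coherence is blind to sign, but the mixed
   component becomes nearly orthogonal to the common mode — so the
   planted structure survives common-average re-referencing instead of
   being subtracted out with the reference. (A uniformly mixed source
   is exactly the average reference and would vanish at that stage.)
3. **Calibrated targets.** Because the finite-window estimator is
   biased, underlying coherences are chosen by inverting a measured
   calibration curve: a 25-point grid of underlying coherence versus
   band coherence measured by the package's own estimator on two-channel
   fixtures (60 segments per point, fixed internal seed), monotonized
   and interpolated, cached per (segment length, Welch settings, band).
   Targets at or below the independence bias floor map to zero mixing.
   Measured planted-minus-background gaps land within ±0.02 of the
   configured effect in expectation.

Ocular artifacts are ~0.35-s raised-cosine deflections (spectral
content < 4 Hz) at a configurable amplitude (default 150 µV) and
Poisson rate (default 6/min), with a fixed frontally dominated
topography (largest at FP1/FP2/FPz); ground-truth event times are
returned alongside.

The clinical table draws pre-treatment PANSS totals from N(74.62,
13.76) clipped to the 30–210 scale, couples the latent change ratio
linearly to each patient's change in characteristic path length
(`ratio = a + b·ΔL + ε`, defaults a = 0.197, b = −2.081, ε ~ N(0,
0.03)), computes post = pre·(1 − ratio) rounded half-even, and
recomputes the realized ratio from the integer scores. Behavioral
indicators are lognormal reaction times and Poisson counts
(Trail-Making errors; Tower-of-Hanoi steps above the 7-move minimum
for 3 disks) with group/task-level parameters matching the emulated
study's group summary tables. In whole-cohort generation the ΔL that
drives the coupling is the *realized* change computed from each
patient's clean recordings with the package's own connectivity and
graph modules, so the prediction stage has a self-consistent target.

**What the generator does not emulate:** volume conduction and field
spread (beyond restricting to 21 widely spaced electrodes), realistic
head geometry, non-stationarity, muscle/cardiac artifacts, band-specific
(theta/alpha/beta) coupling differences, and non-Gaussian background
dynamics. Passing tests establish that the *analysis chain* measures
what it claims on signals with known coupling; they do not establish
sensitivity or specificity on real patient EEG.

## Preprocessing

Filtering is a cascade of 4th-order Butterworth high-pass (0.1 Hz) and
low-pass (45 Hz) sections applied forward and backward: with band edges
three decades apart a single band-pass design is numerically
ill-conditioned. Reflect-padding is scaled to each corner period (the
0.1 Hz cut needs ~20 s of padding; scipy's default leaves a large
startup transient). Steady-state stopband attenuation at 60 Hz is
≈ 21 dB.

Ocular cleaning: FastICA (scikit-learn) with the component count capped
at the numerical rank of the data — after average referencing the
channels sum to zero and a full-rank decomposition would whiten a null
direction into pure numerical noise, which destroys the reconstruction.
Components are flagged as ocular when their time course correlates with
the frontopolar average (|r| > 0.7) or has excess kurtosis > 10.
Flagged components are db4-wavelet decomposed to depth ≤ 8 and
coefficients *above* K = √(2 ln N)·σ̂ are zeroed (σ̂ =
median(|coeffs|)/0.6745 per coefficient array, approximation included —
at depth 8 most blink energy sits in the approximation band). Zeroing
the large coefficients removes the sparse high-energy artifact while
the background signal, which dominates the medians, passes through;
`mode="shrink"` switches to classical hard-threshold denoising.
On blink fixtures this removes ≥ 50% (typically ~80%) of frontal
0.5–4 Hz power while occipital channels stay correlated ≥ 0.99 with
their pre-cleaning versions.

A note on convergence: FastICA cannot converge on rotationally
symmetric Gaussian mixtures (there is no unique independent basis), and
the synthetic background is Gaussian by construction — so non-convergence
warnings on synthetic data are expected and harmless; the heavy-tailed
blink direction is exactly what a kurtosis-seeking iteration locks onto
first, and flagging/cleaning behave correctly regardless. The library
default raises after a retry (real EEG is non-Gaussian and should
converge); the pipeline runs with `on_nonconvergence="warn"`.

Segmentation is non-overlapping 3-s windows, trailing remainder
discarded; segments containing any |sample| > 120 µV are rejected.

## Graph metrics

Edge length is 1/weight (strength convention); the alternative 1 − w is
not used. Shortest paths via Dijkstra (`scipy.sparse.csgraph`); the
brute-force Floyd–Warshall lives only in the test oracles. CLU uses
Onnela clustering with weights normalized by the graph maximum; LE uses
the neighborhood-subgraph weighted efficiency with cube-root
combination. Nodes of degree < 2 contribute zero to CLU/LE.
Disconnected pairs contribute zero to GE and are excluded from L's mean
with a warning; a fully isolated node is an error. With weights in
[0, 1]: CLU, LE, GE ∈ [0, 1] and L ≥ 1, with equality exactly on the
complete unit-weight graph.

One behavioral consequence of max-normalization worth knowing: CLU
measures weight *homogeneity*, not magnitude. A group whose elevation
is confined to a small clique becomes more heterogeneous and its CLU
*drops*; a broad (near-global) elevation raises CLU slightly, because
the coherence estimator's dispersion shrinks at higher coherence. This
is why the demo's treatment effect is predominantly global (below).

## Group statistics

Test selection: Shapiro–Wilk on each sample (differences if paired) at
α = 0.05; normal data get a t-family test — pooled unless the
variance-ratio F test rejects at 0.05, then Welch — otherwise
Mann–Whitney U (reported as min(U₁, U₂)) or Wilcoxon signed-rank. All
tests two-sided. Summary-statistic t-tests are provided so printed
group tables (mean ± SD, n) can be checked directly.

Edge-wise comparison: one independent two-sample t-test per unique
off-diagonal edge, Benjamini–Hochberg FDR over the 210-edge family of a
single contrast (not pooled across tasks), significance masks require
q ≤ α. Zero-variance edges yield p = 1 rather than NaN. On simulated
null cohorts (n = 21/24, 200 repetitions) the any-rejection rate is
≈ 4%; with the 0.3 planted clique effect, planted-edge recovery is
near 100% and false positives among the other 195 edges stay at the
nominal rate.

## Prediction

Features are after-minus-before changes in the four metrics, averaged
over the three tasks by default (`per_task` keeps 12 features and warns
below 3 rows per feature). Collinearity screening computes VIF =
1/(1 − R²) per column and tolerance = 1/VIF; perfectly collinear
columns get infinite VIF and a flag, not an exception. OLS via least
squares with an explicit rank check. LOOCV predicts each subject from
the other n − 1 and reports Pearson r (predicted vs actual) and RMSE in
percentage points of the change-ratio scale; the reported model is
refit on all n. An optional backward elimination drops the least
significant feature until all coefficient p < 0.05 (at least one
feature kept).

**Null behavior of LOOCV r.** Cross-validated predictions are
anticorrelated with the held-out values through the training mean: an
intercept-only model gives r = −1 exactly, and with null features at
n = 21 the mean LOOCV r is ≈ −0.39 (one feature) to ≈ −0.16 (four
features) — *not* zero. The implementation is verified to machine
precision against scikit-learn's `cross_val_predict` with
`LeaveOneOut`. Users should compare an observed r against this
negative null, not against 0; a permutation test is the right tool for
significance.

## Demo study and problem sizes

The shipped demo (`cohnet.pipeline.demo_config`) uses 8 patients, 8
controls, 24-s recordings at 200 Hz (eight 3-s segments per task),
blink artifacts at 6/min, and a treatment effect that is predominantly
global (+0.30 on every edge) with an extra +0.05 on the fronto-parietal
clique, fully removed after treatment, with 30% between-subject effect
variation. The global component is what lets all four metric
directions reproduce simultaneously (higher CLU/LE/GE, shorter L in the
pre-treatment group — see the CLU homogeneity note above); the clique
increment keeps the fronto-parietal edges the strongest individual
differences. The symptom-coupling intercept/slope (0.41, −0.15) are
matched to the ΔL scale this geometry realizes so change ratios land in
the plausible 0.2–0.3 range. The demo's summary edge contrast
(post-treatment vs controls) is computed on task-averaged networks —
one 210-edge family — and is empty, matching the designed absence of a
residual effect.

The operating-characteristic experiments (`cohnet.experiments`) use
full group sizes (21/24) with 12-s recordings at 200 Hz — four segments
per subject — which keeps 200 null cohorts plus 30 effect cohorts
around two minutes on one CPU; the demo pipeline (with ICA per
recording) runs in about one minute. At these sizes every rate quoted
above was measured, and the whole validation suite completes in a few
minutes.

## Known limitations

- Sensor-space coherence cannot distinguish true coupling from residual
  volume conduction; the 21-electrode restriction mitigates but does not
  remove this, and no phase-lag-based measures are implemented.
- A single broadband band is analyzed; band-specific networks require
  re-running with a different configured band.
- The ocular-component rules (correlation/kurtosis thresholds) are
  heuristics tuned for blink-like artifacts; saccades, muscle and
  cardiac artifacts are out of scope.
- The per-task feature mode at realistic n is underdetermined (12
  features, ~21 subjects) and is deliberately warned against.
- PANSS integer rounding quantizes realized change ratios by ≈ 1/pre
  (~0.013), a noise floor for slope recovery at very low noise.
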