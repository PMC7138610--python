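# Methods

## Experimental design being modeled

The pipeline targets trial-based recordings from mouse primary visual
cortex in which serotonergic neurons of the dorsal raphe are photostimulated
(470 nm, 20 Hz, 25 ms pulses) while population activity is measured with
wide-field calcium imaging (100 Hz frame rate) or multi-unit spiking
(0.2 s count bins). Two protocols are represented:

* **trial-train** — 30 s trials with ten 200 ms gratings at 3 s intervals
  (onsets 0.2 + 3k s) and photostimulation from 2.5 s to 18.5 s, so stimuli
  #2–7 fall inside the photostimulated period; four interleaved conditions
  per trial: gratings (V), gratings + photostimulation (V_ph), blank (S),
  blank + photostimulation (S_ph).
* **single-contrast** — one 200 ms grating per trial at contrasts
  100/50/25/12.5/6.25%, photostimulation starting 700 ms before the grating
  and lasting to the end of the trial.

Time is seconds; frames are 0-based; analysis windows are half-open
`[t0, t1)` mapped to frames as `[floor(t0·rate), ceil(t1·rate))` with a 1e-9
guard against float representation error.

## Synthetic-data generator

The generator produces data with exactly the structure the analysis
assumes, with every parameter recorded as ground truth:

* **Ongoing activity** is a stationary Ornstein-Uhlenbeck process (default
  std 0.05 Δf/f, correlation time 1 s), chosen because it matches the slow-
  fluctuation phenomenology and has closed-form moments. The realization is
  keyed by (seed, trial) only, so interleaved conditions of the same trial
  share it — the property that makes trialwise V_ph − S_ph subtraction
  cancel ongoing fluctuations exactly (set `paired_spontaneous=False` for
  independent draws).
* **Evoked transients** are a difference-of-exponentials kernel (rise 0.05 s,
  decay 0.35 s) time-shifted so its unit peak sits exactly at the declared
  peak delay (0.44 s anesthetized, 0.31 s awake, matching the reported peak
  latencies), convolved with the stimulus train and scaled by the
  Naka-Rushton value at the trial's contrast (default R_max 1, c50 0.25,
  n 2, R0 0).
* **Suppression ground truth**: multiplicative gains g_e (evoked) and g_s
  (spontaneous) plus an additive offset, all switching on during the
  photostimulation window. Defaults encode the observed regimes: magnitude
  suppression ratio 0.52 anesthetized vs 0.78 awake (so true g = 1/g_e),
  g_s 0.6, offset −0.05 Δf/f (−0.02 awake). Receptor-antagonist regimes are
  parameter sets, not pharmacology: the 2A antagonist moves g_e to 0.9 and
  attenuates the late ramp; the 1A antagonist sets g_s = 1, offset = 0.
* **Late calcium ramp** — a linear ramp starting a configurable delay
  (default 4 s) after photostimulation onset, growing during
  photostimulation and holding after. It models intracellular calcium
  accumulation and is applied to the imaging modality only; the spiking
  path never carries it, reproducing the calcium-vs-spiking dissociation at
  the generative level. No quantitative onset/slope is established for this
  phenomenon, so the defaults (4 s, 0.02 /s) are free parameters.
* **Spatial model** (movies): `illum(x,y)·(1 + m(x,y)·s(t))` with a smooth
  vignetted illumination map and a Gaussian responsive-region profile
  `m`, plus additive heartbeat (10 Hz) and respiration (3 Hz) sinusoids —
  mouse physiology; the artifacts are named but unspecified in frequency, so
  these are package defaults — a 20 Hz square-wave photostimulation
  artifact confined to the lower-left corner block, and per-pixel Gaussian
  noise. With artifacts/noise off, the ROI mean is exactly affine in the
  injected signal (`roi_affine_coefficients` exposes the coefficients for
  tests).
* **Spiking path**: inhomogeneous Poisson counts with
  `rate = base·G_s·(1 + evoked·G_e) + offset`, base rates uniform on
  0.5–25 Hz so the 1 Hz floor filter and the 1–20 Hz band filter both have
  work to do.

What the generator does *not* emulate: hemodynamic contamination, motion,
indicator nonlinearity and bleaching, spike sorting errors, cell-type
structure, across-trial adaptation. Passing recovery tests therefore shows
the analysis is correct for data satisfying its own assumptions, not that
those assumptions hold in any particular recording.

A separate normalized-scale cohort simulator (`simulate_prepost_cohort`)
draws per-unit pre/post rates directly on the max-normalized scale
(`fr_post = g_s·fr_pre + offset + ε`), the scale on which the regression
coefficients identify ground truth exactly (b4 → g_s − 1, b2 → offset); it
drives the classification-rate studies.

## Preprocessing

Order of operations (logged per run): Δf/f → optional ICA → spatial filters
→ ROI selection → spatial averaging.

* **Δf/f**: each pixel divided by its mean over the first 200 ms of
  recording; the blank average (itself pre-stimulus-normalized by the same
  rule, which makes the stack-equals-blank case exactly zero) is
  subtracted; the result divided by the blank temporal mean.
* **ICA rejection** (off by default, fully logged): FastICA temporal
  sources per trial (default 8 components); a source is rejected when ≥50%
  of its oscillatory power (above a 1 Hz floor) lies within ±0.5 Hz of a
  target band (10, 3, 20 Hz). The floor exists because a gated artifact's
  onset step deposits low-frequency power into the same source and would
  otherwise mask the narrowband concentration. Decomposition failure passes
  the trial through with a warning flag.
* **Spatial filters**: frame-wise Gaussian smoothing (σ = 20 px) then a 2-D
  Butterworth high-pass, magnitude `[1 + (f_c/f)^(2·order)]^(−1/2)`, order
  4, cutoff wavelength 33 px (i.e. f_c = 1/33 cycles/px — the stated
  "cut-off σ = 33 pixels" is read as a spatial wavelength; a temporal
  reading is not implemented because the filter acts frame-wise). DC is
  removed exactly.
* **ROI**: largest 4-connected component above 70% of the evoked-map
  maximum, row-major tie-break — an automated stand-in for manual selection
  of the most responsive region.

## Component metrics

Peak times are located on the control condition (maximum within 1 s of each
onset, earliest-sample tie-break) and reused for photostimulated conditions
so that w1 (400 ms around the peak) is identical across conditions — a
requirement for paired comparisons, and one consistent reading of a
procedure that is not fully specified. Amplitude/baseline are means over
w1/w2; magnitude is their absolute difference. The evoked component
subtracts S_ph from V_ph trial-by-trial when counts match (conditions are
interleaved) and falls back to the S_ph mean otherwise; the fallback is
recorded.

Spike counts are normalized like the traces: spontaneous conditions divided
by the unit's first-second mean (zero-baseline units flagged and excluded),
evoked conditions baseline-subtracted and divided by the control
first-stimulus amplitude.

## Suppression regression and classification

Pre/post windows flank the photostimulation onset (4 s each where the
protocol allows; the trial-train protocol's 2.5 s onset clips the pre
window to the available pre-period). Rates are normalized by the maximum
pre rate over units, which rescales b1/b2 and leaves b3/b4 invariant.
Units below 1 Hz are excluded by default (floor effects); the 1–20 Hz band
is available as the named preset `fig4`. Fits are ordinary least squares
with classical standard errors. Classification runs one-sided one-sample
t tests on per-subject b2 and b4 (suppressive direction, α = 0.05):
divisive / subtractive / mixed / none. Per-subject fits with across-subject
tests are the default (matching coefficient mean ± SEM reporting); a pooled
fit remains available by concatenating records. Fewer than three subjects
skips the tests and labels from point estimates with an `untested` flag.

## Contrast tuning

Naka-Rushton fits use bounded nonlinear least squares (R_max ∈ [0,
10·range], c50 ∈ (0.01, 1], n ∈ (0.1, 10], R0 free) with multi-start over
n ∈ {1, 2, 4}; initialization R0 = min, R_max = range, c50 = median
contrast. All-equal peaks are degenerate (R_max → 0, R0 = level, R² = NaN).
R² is reported whenever the peak range is non-degenerate — the
five-contrast design leaves one residual degree of freedom, which is the
standard usage for these curves. Latency is the first crossing of baseline
mean + 2 SD (700 ms baseline) sustained for ≥2 samples — the persistence
rule resists single-frame noise and is a package choice. Duration is total
time above half of the in-window peak.

## Gain model

g is estimated from magnitude ratios because magnitude is
baseline-independent and isolates the evoked gain; a pooled estimate from
the 100%-contrast amplitude ratio is reported alongside, and both a
per-contrast and pooled g are computed since the ratio's granularity is
ambiguous in principle. Baseline weight is reported both at the control
peak time and averaged over the photostimulation window. The
trace-level identity `V = g·(E_ph + S_ph)` reconstructs exactly on data
built that way; on stochastic data the per-contrast ratio is reliable where
the evoked magnitude clears the trial-averaged ongoing fluctuation (at the
default noise levels, contrasts ≥ 25% with tens of trials).

## Statistics

All t tests are one-sided by default. Zero-variance conventions: zero
effect → p = 1; nonzero constant effect → p = 0, flagged degenerate.
Familywise correction is max-statistic (Westfall-Young style) sign-flip
permutation over the family of paired comparisons: exact enumeration of all
2ⁿ sign patterns when 2ⁿ ≤ 4096, else 10,000 Monte-Carlo permutations with
a logged seed (add-one p convention). Corrected p ≥ raw p by construction.
Onset of significance requires ≥2 consecutive significant bins (same
persistence rationale as latency) under either the −2 SD criterion or the
per-bin corrected permutation test. Detrended comparisons remove each
trace's least-squares line over the full trace and compare residuals within
the stated window — detrending within the comparison window itself would
force both residual means to zero and make the test vacuous.

## Problem sizes and reproducibility

Simulation-backed tests and the acceptance script run at reduced scale as
the package's own default study sizes: 20 Hz trace-level sampling for
trial-train analyses (timing unchanged), 16–32 px movies for image-path
tests, 100-cohort classification studies, 1000-family error-rate
calibration, and a 3-subject end-to-end cohort (32×32 px, 20 Hz, 5
trials/condition). Full-rate (100 Hz) protocols are exercised where the
rate matters (window frame counts, ICA band detection). All randomness
flows through explicit seeds; the pipeline writes a run log (seed, stage
order, parameters, library versions) and its CSV/JSON outputs are
byte-identical across repeated runs at a fixed seed.

## Known limitations

* The ICA rejection rate depends on the component count; the default (8)
  suits small fields of view, and heavily split artifacts can fall under
  the 50% band-power threshold.
* The gain estimate is a ratio of magnitudes and inherits ratio noise at
  low contrast; no shrinkage or error propagation is applied.
* The regression path assumes stationary pre-period rates; slow drifts
  masquerade as subtractive effects.
* MUA and imaging paths share window logic but not a common noise model;
  cross-modality comparisons are qualitative.
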