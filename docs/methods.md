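# Methods

This note documents the models, numerical choices and declared defaults
behind `fearsig`, and what the synthetic-data tests do and do not show.

## Data model and segmentation

A trial is a tri-channel block (ECG mV, GSR µS, SKT °C) at one sampling
rate plus a SAM self-report (valence, arousal, dominance ∈ {1..9}) and
the neutral recovery padding recorded before/after the stimulus
(30 s + 30 s by default).  Sample indices are 0-based, `t = i / fs`, and
windows are half-open sample intervals `[start, start + L)`.  All window
timing is integer-sample arithmetic, so segmentation is bit-exact and
deterministic; trailing samples that do not fill a window are discarded
(every feature operator needs fixed-length input, and the reference
geometry — 60 s stimulus, 20 s window, 10 s step → 5 windows — only
holds without partial windows).  Non-finite samples fail loading rather
than being repaired: the generator is the only expected producer, and
silent interpolation would hide generator bugs.

## Denoising

All filters are linear-phase FIRs (Hamming window), applied by centered
convolution on reflect-padded input: output is sample-aligned with input
(group delay compensated) and start-up transients are suppressed in 20 s
windows.

| filter | cutoff | taps (fs = 256 Hz) | why |
| --- | --- | --- | --- |
| ECG high-pass | 0.5 Hz | 1023 | baseline/DC removal; the transition band of a Hamming FIR is ≈ 3.3·fs/N, so ≥ ~900 taps are needed for the transition to fit below 0.5 Hz — with fewer taps the filter simply does not reject DC |
| ECG low-pass | 40 Hz | 255 | QRS-preserving upper edge; attenuates EMG and mains |
| GSR low-pass | 2 Hz | 129 | covers the 0.05–1.5 Hz phasic band with margin |
| SKT low-pass | 1 Hz | 129 | thermal signals are sub-Hz |

AGC divides the band-passed ECG by a smoothed running amplitude envelope
(moving maximum of |x| over 2 s, 0.5 s moving-average smoothing, floored
at 5% of the global maximum).  It equalizes slow amplitude drift and
makes a fixed relative R-peak threshold valid; with the 2 s window it
equalizes *beat-to-beat* amplitude only when beats are further apart than
the half-window — its role here is gain control ahead of detection, not
morphological normalization.  Peak sample positions are unchanged because
the envelope is locally flat around each maximum.

## Linear features

**R peaks / IBI.** Peaks are local maxima of the AGC output above 0.4
with a 0.25 s refractory period; inter-beat intervals outside
(0.25 s, 3 s) are discarded as ectopic.  Mean IBI and SDNN (sample SD of
the IBI series) are the two time-domain ECG features; SDNN is the most
standard single time-domain HRV statistic.

**Spectra.** All band powers use a single full-window periodogram of the
mean-removed, rectangular-windowed signal, normalized so the one-sided
bin masses sum to the signal variance (Parseval); a 20 s window therefore
has exactly 0.05 Hz/bin resolution.  Welch averaging would coarsen that
resolution and is deliberately not used.  Bands are half-open
`[low, high)`.  Two consequences worth knowing at the 20 s default:
the GSR tonic band [0, 0.05) then contains only the (mean-removed) DC
bin, so `gsr.tonic_power_low` and `gsr.ratio_low` are ≈ 0 at this window
length (they become informative at longer windows); and the four ECG
waveform bands (0–0.4 Hz) lie in the stop band of the 0.5 Hz high-pass,
so they measure residual sub-QRS power.  Both follow directly from the
declared band and filter conventions and are kept for layout stability.

**IBI spectra.** The irregularly sampled IBI series is cubic-interpolated
onto a uniform 4 Hz grid (standard HRV practice) before the periodogram.
LF < 0.08 Hz, MF 0.08–0.15 Hz, HF 0.15–0.5 Hz; the MF ratio uses
LF+MF+HF as denominator, and LF/HF falls back to a flagged 0 when HF is
below machine tolerance.

**GSR decomposition.** Tonic = centered moving median (4 s default,
edges shrink to the valid range); phasic = signal − tonic, so the
decomposition reconstructs the input exactly by construction.  The 4 s
default is longer than any SCR rise and much shorter than tonic drift.
SCRs are detected trough-to-peak: each local maximum of the phasic trace
is paired with the last local minimum before it (for a flat lead-in, the
last point at the segment minimum — the response onset); events below
0.01 µS are dropped.  The method measures the *riding increment* for
overlapping responses; that is inherent to trough-to-peak detection, and
recovery accuracy is therefore assessed on isolated events (see below).

**Quantiles.** Quantiles use linear interpolation between order
statistics.  The default "paper-48" layout merges Q1/Q3 into a single
IQR dispersion value so the registry has exactly 48 names (25 ECG /
17 GSR / 6 SKT); the `"quartiles"` profile emits Q1 and Q3 separately
(49 columns) for users who want both.

**SKT.** Skewness is the standardized third central moment and kurtosis
the Pearson (non-excess) fourth; a zero-variance window yields flagged
zeros for both.

## Non-linear features

ECG and GSR are decimated to 32 Hz (zero-phase FIR) before the
non-linear block.  The recurrence computations are quadratic in window
length, and the dynamics these features target sit far below the
decimated Nyquist (16 Hz); correctness oracles in the test suite run
undecimated on short series.

- **Embedding**: delay T = first local minimum of auto mutual
  information (16 equal-width bins; lag 1 counts when the curve rises
  immediately); dimension M = smallest m with a false-nearest-neighbor
  fraction < 1% (Kennel criteria, R_tol = 15, A_tol = 2).  Near-duplicate
  points (noise-free periodic series) are judged by the absolute
  criterion only, via a floored denominator.
- **Recurrence plot**: threshold E = 10% of the mean pairwise distance
  of the embedded cloud (the "average phase-space diameter" read as the
  mean, not the maximum, which is noise-dominated).
- **RQA**: Theiler window 1 (line of identity excluded from the
  recurrence rate, all line counts and the denominators), l_min = v_min
  = 2.  Note the corner effect: even an all-ones matrix has two length-1
  corner diagonals, so DET is marginally below 1 under this convention.
- **Correlation dimension**: Grassberger–Procaccia slope of log C(r)
  over radii log-spaced between the 5th and 50th percentile of pairwise
  distances.  At the upper end of that range boundary saturation biases
  D₂ slightly low for bounded sets (a uniform square reads ≈ 1.7–1.8
  rather than 2.0); the declared radius range is kept for robustness on
  short windows.
- **Multiscale entropy**: sample entropy (m = 2, Chebyshev,
  r = 0.2 × SD of the original series at every scale) of non-overlapping
  coarse-grained means, scales 1–5.  No-match windows yield flagged 0.
- **DFA**: integrated mean-removed profile, non-overlapping boxes
  log-spaced from 4 to N/4, per-box linear detrend, α = log–log slope
  (0.5 white noise, 1.5 random walk).  The IBI DFA runs on the 4 Hz
  resampled tachogram so a 20 s window provides enough samples.

**Imputation.** Degenerate windows (too few beats, zero variance,
collapsed geometry) never drop a row: affected features become flagged
zeros, keeping the five-windows-per-trial geometry intact.  Extraction is
deterministic — identical window samples give an identical 48-vector.

## Labeling

Fear = the low-valence / high-arousal / low-dominance octant.  With the
1–9 scale split at the midpoint, label 1 ⇔ V ≤ 5 ∧ A > 5 ∧ D ≤ 5.
Assigning the boundary rating 5 to "low" (and to "not high" for arousal)
is a declared convention — a total, deterministic rule is required and
the midpoint itself is configurable.  Exactly 100 of the 729 rating
combinations map to fear under the default.

## Classification and evaluation

Hyperparameters are tuned by sequential model-based optimization: random
exploration (8 points), then a Matérn-5/2 Gaussian-process surrogate on
the unit cube proposing the expected-improvement maximizer among 256
random candidates; default budget 30 evaluations; objective = mean
stratified 5-fold misclassification; fully deterministic given the run
seed.  Spaces: SVM kernel ∈ {rbf, linear}, C ∈ 10^[−3,3], γ ∈ 10^[−3,1]
(log); k-NN neighbors 1–30 (capped at the fold training size), metric ∈
{euclidean, cityblock}, weights ∈ {uniform, distance}; ENS = gradient
boosted trees, 10–300 trees, depth 1–8, learning rate 10^[−2,0] (log) —
boosting is the ensemble of choice for its robustness to class
imbalance.

Subject-dependent protocol: per-subject stratified 5-fold; the reported
value is the fold-averaged validation metric.  Subject-independent:
per-subject z-scoring (each subject against its own statistics — a
per-subject transform, so the held-out subject contributes to no
cross-subject statistic; a train-statistics variant can be had by
z-scoring the training table only), then leave-one-subject-out with
tuning and fitting on the remaining subjects.  AUC credits ties 0.5, so
a constant scorer reads 0.50; Gmean and F1 read 0 for an all-negative
predictor — the standard pathology on heavily imbalanced subjects, which
is why accuracy alone is not trusted.  Aggregation is mean and mean
absolute deviation around the mean.

## Synthetic sessions

The generator emulates the *structure* of a lab elicitation corpus: 12
subjects × 20 one-minute stimuli, 30 s neutral recovery on both sides,
256 Hz, PAD reports coupled to the imposed fear/neutral condition.

- ECG: Gaussian-template PQRST beats at AR(1) RR intervals (φ = 0.8,
  stationary mean 60/HR, SD = SDNN, truncated at 0.3 s), band-limited
  noise at 20 dB SNR by default.
- GSR: tonic level + linear/sinusoidal drift + Poisson SCRs with a
  Bateman kernel (τ_rise = 0.75 s, τ_decay ∈ 2–10 s per event), unit-peak
  normalized.
- SKT: baseline + slow drift + low-pass (< 0.2 Hz) noise.
- Fear effect (stimulus span only, 10 s ramps): HR +8 bpm, SDNN × 0.7,
  SCR rate × 2, SKT − 0.3 °C by default — the standard sympathetic
  activation pattern, declared as a generator convention.  PAD report
  means: (2, 8, 2) fear / (7, 3, 7) neutral, SD 1 scale unit, rounded
  and clipped to 1–9.
- Profiles per subject: HR 55–85 bpm, SDNN 0.02–0.08 s, tonic 2–12 µS,
  SCR rate 1–4 /min, SKT 31–35 °C — physiologically typical adult
  ranges.  Everything is deterministic under the master seed
  (per-subject/per-trial seed streams), and ground truth (beat times,
  SCR onsets/amplitudes, imposed condition) is returned for scoring.

**What passing tests show — and don't.** The synthetic data carries the
imposed autonomic effect in exactly the features the pipeline measures,
with stationary noise and no artifacts.  End-to-end recovery (Gmean ≥
0.9 under a strong effect; LOSO AUC ≈ 0.5 under a null effect) therefore
validates the *plumbing* — labels, splits, leakage-freedom, detectors and
feature determinism — not field performance on real recordings, which
include motion artifacts, ectopy, electrode drift and genuinely
subject-specific emotional physiology.

## Problem sizes and checks

Test and acceptance runs use reduced corpora chosen as representative
slices of the full geometry: the 12 × 20 corpus is generated for the
window-count checks (segmentation only), while classification checks run
on 2 subjects × 20 trials (strong effect, per-subject 5-fold, ENS) and
6 subjects × 12 trials (null effect, LOSO, k-NN).  SCR amplitude
recovery is scored on events isolated by ≥ 20 s, with a 60 s median
window for the standalone decomposition (the tonic estimator window must
exceed the SCR support; the 4 s pipeline default serves 20 s windows
where relative, not absolute, SCR amplitude matters).  Exponent checks
average ≥ 10 seeds.  `scripts/acceptance.py` derives every stream from
`--seed` and writes all quantities to JSON.
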