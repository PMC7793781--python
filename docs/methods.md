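# Methods

This note documents the models, algorithms and numerical choices behind
`gpdcpipe`, and what its synthetic-data validation does and does not
establish about real recordings.

## Data model

A session bundles three index-aligned streams from a 4-channel dry
headband: EEG (μV, 220 Hz; channel order TP09, AF07, AF08, TP10 fixed
left→right), 3-axis head acceleration (m/s², 50 Hz) and a per-electrode
contact indicator (10 Hz; 1 good, 2 acceptable, ≥3 bad). There are no
per-sample clocks — the device timestamps sessions, not samples — so
alignment is by sample index from a common start, and stream durations
must agree within one sample period of the slower stream. Sessions are
the unit of collection and of statistical analysis.

## Synthetic sessions

The generator draws from a stable VAR(p) process
x(t) = Σ A_k x(t−k) + ε(t) with Gaussian innovations — Gaussianity is
the standard simulation choice; the analysis itself only assumes the
MVAR structure. Stability is verified via the companion-matrix spectral
radius; unstable specifications are rejected with the radius reported.
Outputs are rescaled to a per-channel RMS of 20 μV (a realistic scalp
EEG amplitude) *before* artifacts are added, so the 100 μV jump
threshold retains its meaning. Artifacts:

- **Line noise**: a 60 Hz sinusoid of configurable amplitude (5 μV
  default in the demo config).
- **Motion bursts**: amplitude-modulated Gaussian noise (Tukey-tapered,
  α=0.1, so ~90% of the nominal interval carries full amplitude) with a
  co-occurring spike on one accelerometer axis. Modulated noise — not a
  sinusoid — gives ASR a genuine high-variance subspace to find.
- **Dropouts**: contact indicator set to 3 on one electrode for an
  interval.

Acceleration is dynamic-only (no gravity component; see below) with
0.1 m/s² RMS Gaussian jitter. All generation is a pure function of
(specification, seed); cohort generation spawns per-session seeds from
the master seed, so cohorts are byte-reproducible.

The default demo cohort uses 120-s sessions with one burst at 15 s and
one dropout at 100 s — artifacts near the edges so that the required
contiguous clean minute survives — and opposite AF07↔TP10 coupling
(strength 0.4 on a 0.5 diagonal) between the two stages.

What the generator does **not** emulate: 1/f spectral shape, eye-blink
or EMG waveform morphology, non-stationary background rhythms, volume
conduction, or participant-level heterogeneity. Passing tests therefore
demonstrate that the algorithms are implemented correctly and recover
known ground truth under their own model assumptions — not that the
pipeline's scientific conclusions transfer to any particular real
dataset.

## Preprocessing

Fixed order: notch → band-pass → ASR → rule-based rejection → epoching.

- **Notch**: second-order IIR at 60 Hz, quality factor Q = 30 (the
  device applies its notch online; Q is our choice, narrow enough to
  leave 10 Hz power within 1%), applied forward–backward.
- **Band-pass**: 4th-order Butterworth, 1–100 Hz, zero-phase via
  forward–backward second-order sections (effective attenuation is then
  8th-order; "zero-phase" is the interpretation of filtering with no
  phase stage).
- **ASR** (simplified Euclidean form, written for this package):
  calibration uses the *entire* session — per-component robust RMS
  statistics (median, 1.4826·MAD) over 500 ms windows in the basis of
  the eigendecomposition of the element-wise median window covariance.
  Robust statistics keep calibration serviceable even though artifacts
  are included. Processing slides 500 ms windows at a 250 ms step,
  eigendecomposes each window's covariance in calibration space, flags
  components whose RMS exceeds median + 10·(robust SD) — the threshold
  projected onto the window's own eigendirections — zeroes them, and
  reconstructs from the retained subspace with raised-cosine
  overlap-add (windows at 50% hop sum to unity; edges fall back to the
  input where the weight vanishes). A flagged component whose
  channel-space loading exceeds 0.75 in absolute value on a single
  channel marks that channel's subwindows bad in the ASR mask instead
  of being reconstructed: with only four channels, deleting a channel
  outright would end the 4-channel MVAR analysis, so the damage is
  localized in time. No Riemannian variant, no internal randomness.
- **Rejection**: the data are partitioned into 250 ms subwindows
  (55 samples). A subwindow is bad if (a) any electrode's zero-order-
  hold-upsampled contact indicator ≠ 1, (b) any channel's maximum
  absolute first difference exceeds 100 μV (first difference chosen
  over window peak-to-peak as the reading of an "abrupt change";
  differences spanning a boundary belong to the later subwindow), or
  (c) the gravity-free acceleration magnitude exceeds 1 m/s². Gravity
  removal subtracts the per-axis session median before the magnitude —
  a gravity-inclusive magnitude (~9.8 m/s²) would reject everything at
  a 1 m/s² threshold. A session is usable only if some contiguous
  all-good run spans ≥ 60 s; unusable sessions are reported, never
  silently dropped.
- **Epoching**: 6-s epochs (1320 samples) on a 3-s hop grid, kept only
  when every covered subwindow is good — epochs never stitch across
  masked gaps, preserving the local-stationarity assumption of the
  MVAR stage. `kept_fraction` counts clean samples over total samples.

## Connectivity

Each epoch is mean-centered per channel (no detrending) and fitted by
least squares with no intercept; the residual covariance uses the
bias-corrected divisor n − C·p (n = N − p fitted observations). The
Schwarz criterion is SBC(p) = ln det Σ̂_p + (ln n / n)·p·C², with
p-independent constants dropped (argmin unchanged); `select_order`
scans p = 1..p_max over mean SBC across epochs as a diagnostic, while
the pipeline's analysis order stays fixed at 12 for comparability
across sessions. gPDC is evaluated on a 1..50 Hz grid in 1 Hz steps and
summarized over delta [1,4), theta [4,8), alpha [8,12), beta [12,30)
and gamma [30,50] (half-open edges avoid double-counting; gamma's upper
edge is closed). Per-epoch gPDC *magnitudes* are averaged across epochs
(short-time stationary usage; squared-magnitude averaging would be the
main alternative), then band-averaged. The column normalization
Σ_i gPDC² = 1 holds per epoch before averaging; session averages of a
column's squared values need not sum to one.

No time-varying MVAR, no surrogate-based significance of individual
gPDC edges, no source localization — everything is scalp-level.

## Features

Multitaper PSD: "4096 frequency bins on 1–50 Hz" is implemented as a
4096-point zero-padded FFT with the returned grid restricted to
1–50 Hz (literally 4096 bins *inside* 1–50 Hz would imply a ~90,000-
point FFT, which is implausible for 6-s windows). 2·nw−1 = 7 unit-energy
Slepian tapers, eigenspectra averaged unweighted (adaptive weighting
deliberately omitted), one-sided scaling so the full-band integral
equals the variance (validated via Parseval on white noise).

SampEn uses the Richman–Moorman index convention: both template lengths
are counted over i, j ≤ N−m with self-matches excluded, Chebyshev
distance, r = 0.2·SD of the individual window (population SD). Zero
match counts return NaN ("undefined"), never ±∞, and undefined epochs
are excluded from session means with the exclusion count reported —
this per-channel exclusion is also why per-channel sample sizes may
differ in downstream comparisons. SampEn is computed per 6-s epoch
(N = 1320) and session-averaged, like the PSD.

## Statistics

The analysis unit is the session mean. For each metric × location ×
band (or PSD bin) cell, an F-test (F = s²_prep/s²_gen, two-sided
p = 2·min(cdf, sf)) at α = 0.05 selects pooled (equal variances) or
Welch–Satterthwaite (unequal) two-tailed t-tests; the gate's level is a
package choice, as is keeping per-group 95% CIs (mean ± t₀.₉₇₅·s/√n)
rather than difference CIs. No multiple-comparison correction by
default — matching common practice of reporting uncorrected p < 0.05
across a modest grid — with an optional Benjamini–Hochberg flag.
Contiguous runs of significant PSD bins are summarized as frequency
ranges per channel. Cells with fewer than two sessions in either stage
are emitted with a `skipped` flag. Degenerate zero-variance cells keep
the pooled test. Sessions are treated as independent units; no
mixed-effects hierarchy for repeated sessions per participant.

## Problem sizes and numerical notes

Validation simulations use: 100 sessions of 66 s (the generator's
minimum — one clean minute plus edges) for directionality recovery;
50 000-sample series for least-squares consistency checks (coefficients
within 0.02, gPDC within 0.05 of closed form); 2000 null cells of
20 + 20 sessions for type-I calibration; 200 random sequences (N ≤ 200)
for exact SampEn oracle equivalence. Eigendecompositions use symmetric
routines on symmetrized matrices; SBC guards log-determinants by
clipping eigenvalues at a relative floor and raising on singular
covariances; MVAR fitting raises on rank-deficient regressors
(suggesting a smaller order) rather than silently regularizing.

## Known limitations

- ASR is the simplified Euclidean form; its cleaning quality on real
  multi-source artifacts will differ from reference implementations.
- The 0.75 single-channel-loading rule masks time locally; real
  pipelines with more channels would remove or interpolate channels.
- gPDC averaging across epochs has no closed-form null; edge-level
  inference relies entirely on the between-session stage contrast.
- The F-test gate is itself a test on the same data; its error rates
  fold into the overall procedure (the null calibration measures the
  combined behavior, which is why it is tested empirically).
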