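# Methods

`sleeptmr` implements the analysis chain of a targeted-memory-reactivation
(TMR) sleep study — individualized sleep-spindle and slow-oscillation (SO)
detection, SO–spindle phase coupling, cue-locked time-frequency statistics
with cluster-based permutation correction, REM theta power, and
emotional-memory trade-off scoring — together with a synthetic-data
generator that provides ground truth for every stage. This note records the
models, the parameters that matter, and the numerical and design choices,
in the package's own words.

## Analysis chain

**Preprocessing.** Recordings are downsampled to 250 Hz (polyphase,
anti-aliased), notch filtered at 60 Hz (IIR notch, Q=30), high-pass filtered
at 0.3 Hz, and rereferenced to the mastoid average (M1/M2). All frequency
filters are 4th-order Butterworth applied forward–backward
(`scipy.signal.sosfiltfilt`), i.e. zero phase; event-locked latencies are
therefore not biased by filter delay. Cue epochs span −1 to +3 s around
onset and are baseline-adjusted by the mean voltage in the second before
the cue.

**Epoch rejection.** Trials exceeding ±500 µV are flagged "amplitude".
The joint-probability criterion estimates, per channel, the empirical sample
distribution across all epochs (20-bin histogram), scores each epoch by the
mean negative log-probability of its samples, and z-scores that statistic
across epochs; epochs are flagged beyond 6 SD on any single channel or 2 SD
on the channel-pooled statistic. The flag is one-sided: only improbably
*high* negative log-likelihood marks an artifact — an unusually typical
epoch is not one. Rejection only flags; sample values are never modified.

**Hjorth screening of continuous NREM.** Per 30-s epoch (aligned to the
hypnogram) and channel, the three Hjorth parameters — activity (variance),
mobility (RMS angular frequency), complexity — are computed and z-scored
across epochs per channel. A cell is bad when any |z| > 3. Channels bad in
≥25 % of epochs are repaired globally by spherical-spline interpolation;
epochs with >50 % bad channels are removed; remaining bad cells are
repaired epoch-by-epoch; the pass runs twice. The z-score uses a robust
scale (median/MAD): with a mean/SD scale, homogeneous contamination of a
fraction q of epochs caps the attainable z at √((1−q)/q), which is below 3
for q ≥ 0.1 — the ≥25 %-of-epochs channel rule would be unreachable by
construction. If an epoch cannot be repaired because fewer than 4
positioned good channels remain (small montages), it is dropped rather than
erroring.

**Spherical splines.** Perrin-style interpolation with order m=4, 50
Legendre terms, and ridge regularization 1e-5 on the kernel matrix;
positions come from the standard 10-20 montage shipped with MNE. Validated
on a constant field (exact to 1e-6) and a smooth dipolar field (r > 0.95 at
a removed central channel).

**Spectral peaks.** Power spectral density uses Welch's method with 5-s
Hamming windows and 50 % overlap, computed on the first difference of the
signal scaled by fs (a d/dt approximation) to whiten the 1/f background and
make band-limited peaks prominent. The individualized peak is the in-band
local maximum with greatest topographic prominence (height above the higher
flanking in-band minimum); ties break toward higher prominence, then lower
frequency. Bands: fast spindle 12.5–16 Hz, theta 3–8 Hz. With no in-band
local maximum the band midpoint is returned with an explicit
`fallback_used` flag. REM spectra are normalized per channel by that
channel's mean power (so the normalized mean is identically 1) before
averaging ±1.5 Hz around the theta peak; the normalization divisor uses the
same artifact-free REM data as the peak search.

**Spindle detection.** The signal is convolved with a complex Morlet
wavelet at the individual peak frequency with a 3 Hz spectral FWHM
(σ_f = FWHM/2.355; σ_t = 1/(2π σ_f) ≈ 0.125 s). The wavelet is
L1-normalized so a unit-amplitude in-band sinusoid gives magnitude ≈ 1.
Events are runs where the magnitude exceeds 9 × its median over
artifact-free samples for ≥ 400 ms; the 9× threshold is applied to the
magnitude (not squared magnitude), reading "median signal amplitude"
literally. Supra-threshold runs separated by < 100 ms are merged first to
avoid double-counting envelope dips. A zero median (degenerate threshold)
yields no detections plus a warning. Events overlapping artifact-masked
samples are discarded. Event amplitude is the magnitude maximum; peak time
is its location.

**SO detection.** The 0.5–4 Hz (delta) filtered trace is scanned for
positive-to-negative zero crossings; spans between consecutive crossings
lasting 0.8–2 s (0.5–1.25 Hz) are candidates, and the top quartile by
peak-to-peak amplitude per channel is retained (⌈n/4⌉ events).

**Coupling.** A spindle is coupled when its amplitude peak falls inside a
retained SO span. The coupling phase is the analytic-signal angle of the
delta-filtered trace at the spindle peak, with 2 s reflection padding
around the Hilbert transform. Phase convention (stated because conventions
differ across labs): 0° at the SO positive peak, ±180° at the trough,
increasing through the falling flank. Summaries: coupled density (events
per artifact-free NREM minute), circular mean phase, and resultant vector
length.

**Cue-locked time-frequency.** Complex Morlet decomposition at 30
log-spaced frequencies 2–40 Hz with 5→10 cycles (log-spaced), at Cz by
default. Trial-averaged power is decibel normalized,
10·log10(P/P_baseline), against mean power 500–200 ms pre-cue (the gap to
onset avoids temporal leakage of post-cue activity into the baseline).
Spindle probability is the across-trial mean of a per-sample spindle
indicator. Condition trial counts are equalized by seeded random
subsampling of the larger condition.

**Cluster-based permutation test.** Pointwise paired t statistics are
thresholded at two-tailed p < 0.05 (the cluster-forming threshold is a
declared default — it trades cluster sensitivity for specificity and is not
derived from data). Contiguity is 4-connectivity on time×frequency maps and
run-adjacency on 1-D maps. The cluster statistic is t_sum, the sum of
member t values. The null distribution is the maximum |t_sum| over clusters
of either sign under random within-participant sign flips of the condition
difference — the exact permutation scheme for a paired design — with
corrected p = (1+b)/(1+B). Permutation t maps are computed by a single
matrix product over sign-flip vectors (the per-participant squared
differences are flip-invariant), so 1,000 permutations on a 20×40 map cost
milliseconds. Calibration: over 200 null simulations (n=20), the familywise
false-positive rate is ≈ 0.05; an injected 1-dB, 5-bin × 0.5-s patch on
unit-variance participant noise is recovered with ≥ 70 % overlap in
essentially all runs.

**Behavioral scoring.** Corrected recognition = hit rate − false-alarm
rate, per participant and condition (emotion × component × cue). Object
false alarms are per emotion; background lures are all neutral, so one
pooled background rate is used. Cueing benefit = cued − uncued corrected
recognition. Group inference: one-sample t tests per component with
Benjamini–Hochberg FDR adjustment (the step-up procedure, via
statsmodels); robust regression is iteratively reweighted least squares
with Tukey bisquare weights, tuning constant 4.685, convergence tolerance
1e-8 (statsmodels RLM); circular–linear correlation uses
r² = (r_xc² + r_xs² − 2 r_xc r_xs r_cs)/(1 − r_cs²) with the asymptotic
n·r² ~ χ²(2) p value; the Watson–Williams F test compares mean directions
of two circular samples, with a validity flag when the pooled resultant
length falls below 0.45. Linear mixed-effects modeling is deliberately out
of scope: `to_long_format` exports a tidy table for external fitting.

## Synthetic-data generator

The generator is first-class, tested code; it defines the conditions under
which every downstream claim is verified.

* **Background**: per-channel Gaussian noise with power ∝ 1/f^slope
  (default slope 1.0), RMS-calibrated to 15 µV (mastoids 2 µV). Shaping is
  done in the frequency domain; DC is removed.
* **Spindles**: Hann-windowed sinusoidal bursts. Each simulated participant
  has a fast-spindle peak frequency (drawn from the central half of
  12.5–16 Hz unless fixed) and per-event frequencies jitter around it with
  SD 0.3 Hz — individuals have concentrated spindle peaks; a uniform spread
  over the whole band would contradict the premise of peak
  individualization. Durations are uniform on 0.5–2 s; default rate
  4/min; default amplitude gain 10× background RMS. Event placement is
  non-overlapping; fixed-count placement (rate × minutes) is the default so
  tests can assert exact counts, Poisson placement is selectable.
* **SOs**: one cycle of −sin(2πt/T), T drawn from 0.8–2 s, negative
  half-wave amplified ×1.2, so the span between positive-to-negative zero
  crossings exists by construction; default gain 10× background RMS.
* **Coupling**: a configurable fraction of SOs carries a spindle whose
  envelope peak sits at an SO phase drawn from von Mises(µ, κ). The
  phase→time mapping inverts the phase of the isolated SO template measured
  exactly as the analysis measures it (0.5–4 Hz filter + Hilbert), so
  waveform asymmetry and filter shaping cancel and the generator's "true
  phase" and the detector's phase share one definition.
* **Event gains** are always in units of the *background* RMS, estimated
  robustly (1.4826 × median absolute deviation), which is insensitive to
  previously injected sparse events — naive SD-based scaling compounds
  amplitudes across injection passes.
* **Cue protocol**: blocks of 46 memory sounds (23 negative, 23 neutral)
  plus 6 controls, shuffled per block, 5-s inter-stimulus interval,
  delivered only in N2/N3 after an initial uninterrupted-NREM criterion
  (default 300 s); delivery pauses across arousals/stage shifts and resumes
  in NREM. Responded cues (per-category probabilities, default 0.7 memory /
  0.2 control) receive a theta packet (5.5 Hz, 0.6 s, centered 0.675 s
  post-cue, gain 6× RMS) and a spindle burst (participant spindle
  frequency, 0.7 s, centered 1.05 s post-cue, gain 8× RMS), with 80 ms
  latency jitter. The response gains are free parameters of the simulator
  — the physical effect sizes of real cue-evoked responses are not pinned
  down — and are recorded in the configuration, not claimed as data.
* **Hypnogram**: schematic night (wake/N1 onset, alternating 5-min N2/N3
  bouts, REM tail over the final 15 %), sufficient for stage bookkeeping;
  it does not emulate real sleep-cycle ultradian structure.
* **Behavior**: item-level old/new responses — 368 recognition trials per
  participant (4×23 old objects, 4×23 old backgrounds, 2×46 new objects,
  92 new backgrounds). Participant rates are logit-normal around the
  configured condition means (defaults follow the modeled study's group
  means) with a shared participant offset (SD 0.5 logits) plus cell-level
  noise (SD 0.25); the logit-scale location is mean-corrected by
  Gauss–Hermite quadrature so the probability-scale group mean equals the
  configured mean for any spread. Response counts are binomial; a
  `deterministic_counts` mode uses rounded expected counts so that, with
  zero spread and grid-aligned means, empirical rates reproduce the means
  exactly.

**What passing tests do and do not show.** The generator produces
additive, morphologically clean events on stationary 1/f noise. Passing
recovery tests demonstrates that the detectors and statistics are
implemented correctly and are well calibrated under the stated event
morphology and signal-to-noise; they do not certify performance on real
sleep EEG, where spindles wax and wane asymmetrically, SOs travel across
the scalp, artifacts are structured, and the background is nonstationary.
The cluster-test calibration, by contrast, is distribution-free at the map
level and carries over directly.

## Problem sizes

Detector and coupling benchmarks use 20–40 min single-channel records (80
spindles, 100–200 SOs); cluster calibration uses 200 null and 20 effect
simulations of n=20 participants with 1,000 permutations on 20×40 maps; the
end-to-end cohort check uses 12 participants × 1 h sessions. These sizes
were chosen so each quantity's Monte-Carlo error is small relative to its
acceptance band while the whole suite stays interactive.

## Known limitations

* Single-channel event analysis in the pipeline (Cz by default); the
  detectors accept any channel but no cross-channel event consolidation is
  implemented.
* The Watson–Williams test and circular–linear correlation use asymptotic
  reference distributions; small-sample exactness is not attempted.
* EDF/BrainVision export is not provided (reading only); the native
  exchange format is the HDF5 fixture container.
* The joint-probability estimator is histogram-based (20 bins); kernel
  estimators would differ in detail. Its thresholds follow the 6 SD /2 SD
  convention of the modeled pipeline.
* `mne`'s Morlet TFR applies no epoch padding: bins whose wavelet support
  exceeds the distance to the epoch edge are edge-attenuated; with the
  −1 to +3 s epochs this affects frequencies below ≈ 6 Hz near the epoch
  boundaries (including part of the baseline window at 2–3 Hz).
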