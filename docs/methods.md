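# Methods

This note documents the models, conventions and numerical choices behind
`locorhythm`, and what the synthetic-data validation does and does not
establish about real recordings.

## Signal model and preprocessing

A fictive-locomotion neurogram or EMG channel is modelled as episodic
bursting: per locomotor cycle of period T, a burst envelope of duty
fraction d is filled with broadband multi-unit activity and rides on
baseline noise. Preprocessing converts the raw trace (sampled at a few
kHz) into a form where cycle-scale structure dominates:

1. window the recording into non-overlapping 60-s intervals, tiling from
   t = 0 (partial trailing windows are dropped);
2. full-wave rectify;
3. zero-phase low-pass filter and resample to 100 Hz;
4. subtract the mean;
5. smooth with a 13-point, 3rd-order Savitzky–Golay filter
   (mirror-padded edges, so trace length is preserved without zero-edge
   artifacts).

The low-pass **cutoff defaults to 5 Hz** with a 4th-order Butterworth
applied forward-backward. The cutoff and family are package choices
(exposed as `cutoff_hz` / recorded in `ProcessedSegment.params`):
locomotor rhythms here are below ~1 Hz, and 5 Hz keeps burst edges sharp
enough for onset detection while removing the carrier. Resampling is
polyphase with anti-aliasing (`scipy.signal.resample_poly`,
`padtype="line"`), output length `round(n·fs_out/fs_in)`, non-integer
ratios allowed. Mirror-edge smoothing can shift the mean by a tiny
amount, so the chain removes the mean once more after smoothing; this
guarantees the zero-mean contract (|mean| < 1e-9·SD per channel).

The whole chain is deterministic and positively homogeneous: scaling the
input by a > 0 scales the output by a, so all downstream statistics are
amplitude-invariant (amplitudes of real preparations are
electrode-dependent and carry no meaning here).

## Correlograms

For processed channels x, y, C(ℓ) is the Pearson correlation of the
overlapping portions of x(t) and y(t + ℓ), evaluated on a symmetric lag
grid at the processed sampling interval (10 ms at 100 Hz) by default; a
strict 50-ms grid is available via `lag_step_s`. Lags whose overlap has
zero variance, or fewer than 10 overlapping samples (when the signal
itself has at least 10), are NaN and excluded from peak searches.
Extrema are local maxima/minima with prominence ≥ 0.05 over the grid;
ties break toward the smallest |lag|.

## PTCC (rhythm stability)

The *signed* PTCC (default) is C(e₀) − C(e₁): e₀ is the extremum nearest
lag 0, e₁ the first later extremum of the opposite kind within the
search window. A stable synchronous pair has a peak near +1 at lag 0 and
a trough near −1 at T/2, giving PTCC → +2; a stable alternating pair has
the mirror geometry, giving PTCC → −2. The sign therefore encodes the
coordination mode and the magnitude its stability, matching how signed
stability values are reported for synchronous vs alternating pairs in
this literature. A *literal* mode — first positive-lag peak minus the
window minimum, always ≥ 0 — is retained as an option; the two
definitions coexist deliberately because the non-negative formula cannot
produce the negative values conventionally reported for alternating
pairs.

The `ptcc` primitive searches the first 75 lags of 50 ms (3.75 s of
positive lag). For slow rhythms (T ≳ 7.5 s) the first opposite extremum
at ~T/2 falls outside that window, so the composite `analyze_pair`
widens the window to max(3.75 s, 0.75·T) once the cycle period is
measured; without this, slow but perfectly stable rhythms would be
flagged `no-peak-found`.

## Cycle period and phase lag

T is the lag of the first off-zero autocorrelogram peak (prominence
≥ 0.05); absence of such a peak raises the `weak-rhythm` flag. For a
pair, T comes from the **first** channel's autocorrelogram (a
convention; the two channels' periods agree whenever a coordinated
rhythm exists).

Phase lag (default *peak-lag* mode): find the cross-correlogram trough
nearest lag 0 within [−T, +T], then the first peak at a greater lag;
φ = (peak lag mod T)/T ∈ [0, 1). This yields φ ≈ 0 for synchronous and
φ ≈ 0.5 for alternating pairs. The *literal* mode (trough-to-peak
distance divided by T) is retained but gives 0.5 for **both** regimes on
ideal signals — the trough sits at ±T/2 for a synchronous pair and at 0
for an alternating one, and the next peak is T/2 away in either case —
so it cannot separate the regimes and is not the default.

Classification: synchronous if |PTCC| ≥ 0.3 and φ within 0.25 of 0
(circularly); alternating if |PTCC| ≥ 0.3 and |φ − 0.5| < 0.25;
otherwise indeterminate. Both thresholds are exposed. Note φ = 0.25 sits
exactly on the class boundary and is deliberately indeterminate.

## Burst detection and circular statistics

Detection is a Schmitt trigger on the processed trace: a burst starts
when the signal exceeds 0.30·A and ends when it drops below 0.15·A,
where A is the 95th percentile of the rectified trace (robust to
occasional large deflections). Gaps < 0.2 s are merged, bursts < 0.2 s
dropped; all four parameters are configurable, since no standard rule
exists and published analyses rarely state one.

Onset phases are target-onset-within-reference-cycle: a target onset t
in reference cycle [onᵢ, onᵢ₊₁) has phase (t − onᵢ)/(onᵢ₊₁ − onᵢ),
normalized 0–1 (multiply by 360 for degrees). The resultant length
R̄ ∈ [0, 1] measures coupling strength; Rayleigh's Z = nR̄² with the
second-order series p-value

p = e^(−Z)·[1 + (2Z − Z²)/(4n) − (24Z − 132Z² + 76Z³ − 9Z⁴)/(288n²)],

clipped to [0, 1]. The series agrees with the Wilkie approximation used
by other packages to ~1e-3 at moderate n. Because phases are continuous
there is no exact enumeration analogous to a sign-flip permutation; for
very small n a seeded Monte-Carlo null (`rayleigh_test(..., method="mc")`)
is provided instead.

## Gait ratios

Only along-track (x) coordinates enter the ratio. For each right-paw
stride [xᵢ, xᵢ₊₁) of length R, L is the distance from xᵢ to the left
print within the stride (`nearest` mode takes the smallest L; a
`midpoint` mode takes the print nearest the stride midpoint). The raw
ratio L/R is folded to [0, 0.5] — a left print at 0.9 of the stride is
0.1 from the nearest right print — so 0 means synchronous (hopping) and
0.5 perfect alternation, and the statistic is insensitive to which
right print a noisy near-coincident left print happens to fall beside.
Per-run value = mean over stride pairs; per-animal value = mean over
runs (typically three). The ratio is translation-invariant and
scale-invariant.

## Group statistics

Implemented on scipy.stats: pooled-variance two-tailed t by default
(Welch selectable), Mann–Whitney U with exact enumeration p for
min(n) ≤ 8 tie-free samples (tie-corrected normal approximation
otherwise), Wilcoxon signed-rank (zero differences dropped, exact for
n ≤ 15 tie-free), one-way ANOVA + Tukey HSD via the studentized-range
distribution. "Choose by data distribution" is operationalized as a
Shapiro–Wilk screen on each group at α = 0.05 (`method="auto"`); groups
with n < 3 fall back to the rank test.

Effect sizes: Cohen's d = (mean_a − mean_b)/pooled SD. Rank-biserial
r = 1 − 2·U_a/(n_a·n_b) with U_a the count of (a, b) pairs where a > b
(ties ½), so **r > 0 means group b tends larger**; the opposite
convention is the negation. The sign convention is stated here and in
the docstring because published reports often omit it.

## Synthetic generator

`simulate_neurogram` realizes per-cycle periods T·εₖ with εₖ lognormal,
mean 1 and coefficient of variation `period_jitter_cv` (0 = metronomic);
phase offsets are applied *within* each jittered cycle, so left-right
coupling survives jitter, as in coupled half-center models. The burst
interior is |zero-mean Gaussian| scaled by the envelope — a rectifiable
stand-in for multi-unit population activity (when `carrier_noise_sd` is
0 the carrier is the constant 1, giving the deterministic envelope);
baseline noise is additive Gaussian. Carrier SNR is defined as
amplitude·carrier_SD / baseline_SD; validation uses SNR 5 (amplitude 1,
carrier SD 1, baseline SD 0.2), a moderately noisy but usable recording.
Defaults mirror typical preparations: T = 5 s, duty 0.5, 60-s windows,
2500 Hz sampling, 2–4 channels. Footprints lie along a 1-m track with
right-hind prints at k·stride, left-hind at (k + offset)·stride, 6-cm
stride, 0.1-cm placement noise, 2-cm lateral spacing.

What the generator does **not** emulate: slow amplitude drift, episodic
rhythm dropout, electrode artifacts, inter-animal variability in duty
cycle, bout-limited rhythms, or correlated noise across channels.
Passing parameter recovery therefore shows the estimators are unbiased
and precise under the stated signal model, not that they are robust to
every pathology of real recordings; the quality flags (`weak-rhythm`,
`no-peak-found`, `indeterminate`) exist to surface such cases rather
than mask them.

## Validation scales

The validation grid uses 90 simulations (3 periods × 3 offsets × 10
seeds) of 60 s each, 2000 Monte-Carlo sets for the Rayleigh null,
100 random pairs for the correlogram oracle, and 5 × 6 footprint runs
of 20 strides; these sizes give stable fractions while keeping the full
validation around a minute on one core. Parameter-recovery runs use
zero period jitter — the grid probes estimator accuracy, while jitter
robustness is exercised separately in the unit tests.

## Known limitations

- PTCC/phase need at least ~3 cycles per window; very slow rhythms
  (T > ~20 s with 60-s windows) go undetected by design.
- Phase lag is a per-window summary; time-resolved phase drift within a
  window is out of scope.
- The Schmitt-trigger amplitude reference (95th percentile) assumes
  bursts occupy a substantial fraction of the window; a window with a
  single brief burst will under-threshold.
- The Rayleigh series p-value is an approximation; below n ≈ 10 prefer
  the Monte-Carlo option.
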