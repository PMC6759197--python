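# Methods

This note documents the models, estimators and numerical choices behind
`locorhythm`, and what the synthetic-data validation does and does not show
about real recordings.

## The signal model

Fictive locomotion in the isolated neonatal rodent spinal cord appears on a
ventral root as broadband multi-unit discharge whose *envelope* is rhythmic:
alternating bursts at 0.1–0.9 Hz, with left/right flexor roots ~180° apart
and ipsilateral flexor/extensor roots ~180° apart.  All downstream
quantities (frequency, phase, burst pattern) live on the envelope, not the
carrier.  The synthetic generator therefore models a recording as

    trace_c(t) = A_c · [ b·n0(t) + m_c(t) · env_c(t) · carrier(t) ]

where `carrier` is zero-mean broadband Gaussian noise at 10 kHz (a sparse
spike-train carrier is available but the integration cascade makes the two
indistinguishable downstream), `n0` is baseline instrument noise
(`b = 0.05` of channel amplitude), `env_c` is a periodic rectangular pulse
of the channel's programmed duty cycle and phase offset with raised-cosine
edges (default 10 % of the cycle), and `m_c(t)` applies the light-epoch
amplitude factor.  One phase oscillator drives all channels; its
instantaneous frequency is the programmed `f(t)` (base frequency, scaled by
the light factor inside the illumination window).  In the hemicord scenario
the oscillator is frozen for the programmed tonic-onset duration while the
envelope is clamped elevated (1.5× burst amplitude — the recordings show
intensified discharge at light onset) and non-oscillatory.

Ground truth (exact `f(t)`, square-edge burst onset/offset times, duty
cycles, phase lags, per-epoch amplitudes, spike times, bleach parameters) is
exported with every simulation; all randomness derives from one root seed
through named `SeedSequence` children, so output is bit-reproducible and
adding channels or trials never perturbs earlier draws.

### Scenario presets and cohort draws

Three presets program the study conditions: a whole-cord drug scenario
(0.33 Hz slowed to 0.29 Hz by the light; pre-light duties extensor
0.59 ± 0.04, flexor 0.53 ± 0.07; flexor burst duration ×1.402 ± 0.1525 and
extensor ×1.1963 ± 0.2237 under light), a hemicord scenario (0.10 ± 0.02 Hz
with a 10 s tonic onset, then 0.17 ± 0.06 Hz; extensor duration
×0.6061 ± 0.2236, flexor ×1.1268; pre duties flexor 0.35 ± 0.06 / extensor
0.61 ± 0.09), and a dorsal-root-evoked scenario (4 Hz, 10 s trains;
0.89 Hz control rhythm; light reduction 21.6 % ± 10.23 %).

Per-experiment heterogeneity uses **stratified (moment-matched) draws**: the
inverse normal CDF at equal-probability stratum midpoints, randomly
permuted.  Each experiment's marginal distribution is the stated truncated
normal, but the cohort mean and SD equal the programmed population values —
the point of a parameter-recovery cohort is to test the pipeline, not the
luck of an i.i.d. draw whose mean at n = 12–16 wanders by an amount
comparable to the recovery tolerances.  Midpoint draws at these n lie
within ±2 SD automatically.

Two structural couplings keep the implied parameters physical.  Pre-light
and light-epoch hemicord frequencies are rank-coupled (faster baselines stay
faster under light, consistent with the positive control-vs-light frequency
association in these preparations), and burst-duration factors are
rank-anti-paired with the frequency speed-up (the largest duration drops
co-occur with the largest accelerations), which encodes that duty cycles
are more conserved than durations and keeps every implied light duty cycle
inside (0, 1).  Marginal distributions are unchanged by these pairings.
Within-experiment trial-to-trial variability is not reported for these
preparations; presets expose it as a free parameter, default 5 % of the
base frequency.

## Integration and resampling

The envelope ("integrated neurogram") is low-pass 200 Hz → high-pass
10 Hz → |·| → low-pass 5 Hz (drug) or 20 Hz (evoked).  Filter family and
order are not dictated by the procedure itself; we use 4th-order
Butterworth stages applied zero-phase (`sosfiltfilt`, odd-reflection
padding, pad length 3× an impulse-response proxy) because every downstream
metric depends on burst *timing*, which causal filtering would skew.
Resampling to 19 Hz is polyphase and anti-aliased.  A hard-edged (square)
envelope rings by several percent at the final low-pass; realistic,
band-limited burst envelopes stay non-negative to within 1 % of peak.

## Wavelet rhythm tracking

Complex Morlet with center-frequency parameter ω₀ = 6 (PyWavelets
`cmor2.0-0.9549`), 300 log-spaced frequencies over [0.05, 2] Hz (drug) or
[0.2, 4] Hz (evoked), time axis binned to 3,200 points.  Two numerical
details matter:

* **Scale mapping.** Scales are computed analytically as
  `s = C·fs/f` with the wavelet's exact center frequency C.  PyWavelets'
  numeric `central_frequency` is FFT-bin quantized and would bias *every*
  ridge frequency by ~2 %.
* **L1 renormalization.** Coefficients are divided by √s so equal-amplitude
  tones have equal ridge magnitude at all scales; without it the band
  argmax drifts toward low frequencies.

The frequency series is the per-bin magnitude argmax over the band,
median-smoothed over 5 bins (grid quantization is ~0.6 %, i.e. ±0.002 Hz at
0.33 Hz).  Phase between channels is the argument of the cross-wavelet
coefficient at the reference (first-named) channel's ridge, wrapped to
[0, 360); positive values mean the reference leads.  10 s are trimmed at
each end (edge effects); percent-change normalization divides by the
pre-light mean, subtracts 1, multiplies by 100.  Missing bins propagate
through normalization and averaging (pairwise-complete means).

## Tonic-segment detection

The hemicord scenario interposes a sustained, non-oscillatory discharge
between light onset and the resumed (faster) rhythm.  Frequency statistics
must exclude it.  Detection is envelope-domain: the smoothed envelope is
thresholded at the mid-level between its baseline 10th and 90th
percentiles (the baseline *median* sits on the burst edge when the duty
cycle is near 0.5 and fragments runs), and an elevated run is flagged tonic
when its level exceeds the baseline burst-peak level (1.1× the baseline
P90) or when it outlasts 1.4× the median baseline high-run — an envelope
that fails to dip where the rhythm's duty cycle says it must.  Flagged runs
are refined to the interval where the envelope stays above 0.7× the run's
plateau level, which puts the boundaries on the tonic plateau's own edge
ramps.

A purely spectral criterion was rejected: a ~10 s plateau has genuine
rhythm-band energy near 0.1 Hz, and the Morlet support at these frequencies
(≈ one period, several seconds) smears any power measure across the
boundary, far beyond the ±2 s accuracy the scenario requires.  Two
limitations follow.  When tonic and burst amplitudes are equal, a burst
merging into the plateau is not identifiable and the extent is
overestimated by up to one burst duration.  And ridge estimates *near* a
tonic boundary are contaminated over the wavelet support, so epoch means
drop bins whose distance to a tonic interval is less than 1.5 periods *of
that bin's own ridge frequency* — spurious low-frequency ridge values near
the transient carry long support and thereby exclude themselves.

## Burst segmentation and metrics

Cycles are segmented by **hysteresis** on the envelope's robust range
(P5–P95 after slow adaptive gain normalization by a rolling 90th
percentile over ~2.5 expected periods): a burst is a run above the 30 %
level that reaches the 55 % level.  Splitting a burst therefore requires a
dip through most of its amplitude — not carrier ripple — and bridging a gap
requires noise to fill most of the gap's depth.  Runs/gaps shorter than
15 % of the minimum period are dropped/merged, and bursts whose midpoints
are closer than the minimum period (default half a period of the fastest
band frequency; the pipeline passes 0.5/f̂ from the ridge) are merged.
Peak-prominence detection with an interquartile-range floor was tried
first and rejected: the IQR collapses for duty cycles away from 0.5, and
at realistic noise the prominence distributions of plateau ripple and of
smoothing-attenuated interburst gaps overlap.  The adaptive gain stage
makes segmentation insensitive to the strong light-epoch amplitude
modulation (up to ~2.4× on extensor channels), which otherwise leaves
pre-light bursts below a globally chosen level.

Burst boundaries follow the fractional rule: onset is the last upward
crossing of `trough + 0.4·(peak − trough)` before the peak, offset the
first downward crossing after it, with the *following* trough's level on
the falling edge (symmetric treatment, robust to slow drift) and
sub-sample linear interpolation (19 Hz quantization, ~53 ms, is too coarse
for sub-second bursts).  On noisy envelopes the crossing levels use a
±2-sample average around each extremum, and the envelope is pre-smoothed by
a 0.3 s moving average; on clean waveforms (halfwidth 0, no smoothing) the
triangular-burst duration is exactly 0.6× the base and a square pulse's
duration is its width at any threshold.

Known bias: a raised-cosine edge of width w crosses the 40 % level
0.064 w outside the nominal square edge, so measured duty cycles carry a
positive offset of ≈ 0.128 w per cycle — ≈ +0.013 at the default 10 %-of-
period edge.  This is a property of the 40 % rule on band-limited edges,
not of the detector; it is well inside the ±0.02 recovery tolerance and
cancels in duration *ratios*.

Per-cycle metrics: duration, interburst interval (offset to next onset),
amplitude (peak − preceding trough), period (onset to next onset), duty =
duration/period; duration + interval = period by construction.  Cycles are
labeled by the epoch containing the peak; bursts that straddle an epoch
boundary are dropped from per-epoch statistics and cycles whose period
spans one lose their period metrics, since they reflect neither condition
(the generator switches parameters discontinuously at the boundary; real
transitions are smoother, so on real data this filter is conservative).
Averaging order is cycles → trial → experiment → group, and percent changes
are with respect to the pre-light epoch.

## Bootstrap time-series comparison

Experiments are the independent replicates, so the bootstrap resamples
experiments with replacement (never timepoints or trials).  Per bin the
observed statistic is a Welch t (group sizes differ, e.g. 16 vs 9); the
null recenters each group on the pooled mean before resampling; the
two-sided p uses the +1 correction so finite iterations never give p = 0.
Resampling is vectorized through multinomial count matrices (two matrix
products per group for all iterations and bins).  Inference is pointwise
with no multiplicity correction, matching the banded display
(ns, <0.05, <0.01, <0.001, <0.0001; strict inequalities, p = 0.05 is ns);
a family-wise max-|t*| option exists but is off by default.  Null
calibration at nA = 16, nB = 9 is verified to hold within [0.03, 0.07] at
the 0.05 band.

## Circular statistics

Angles are degrees at the interface, radians internally.  Mean direction
and resultant length R come from the unit-vector resultant (mean undefined
at R = 0).  The Rayleigh p uses the standard finite-n approximation.
Watson–Williams uses the multi-sample F with the 1 + 3/(8κ̂) correction,
κ̂ estimated from the within-group mean resultant length (Fisher's
piecewise approximation); concentrations below r̄ = 0.45 attach a warning
rather than fail, since the test is routinely applied to small phase
samples.  Harrison–Kanji decomposes row/column/cell resultants — row and
column resultants are vector resultants over all angles at a level, not
sums of per-cell magnitudes, an error that inflates the factor effects
several-fold — with the high-concentration F variant (β = 1/(1 − 1/(5κ) −
1/(10κ²))) for κ̂ > 2 and the low-concentration chi-square variant
otherwise.  Full (statistic, df, p) are always reported.

## Intracellular analysis

Spikes are upward crossings of a −20 mV threshold confirmed by
dV/dt ≥ 10 V/s, with a 3 ms refractory period; both thresholds are
configurable.  For the drive, the trace is decimated to 1 kHz and median-
filtered (15 ms) to remove spikes, each onset-to-onset cycle is resampled
to 200 phase bins, and the mean ± SD over cycles is displayed across two
cycles; drive amplitude is max − min of the mean waveform and trough
potential its minimum (per-cycle extrema are available as an alternative;
CTA extrema are the default because they are far less noise-inflated at
small cycle counts).  Input resistance is the OLS slope of the
current/voltage relation over the largest contiguous subset of steps whose
residuals stay below 2 % of the voltage range, excluding saturating
extremes.  The liquid junction potential is not corrected.

## Calcium traces

Grid ROIs are six equal rectangles tiling the field dorsoventrally (an
indivisible height goes to the last ROI).  Cell ROIs pair with a doughnut
annulus out to twice the cell radius, excluding other cells' pixels, whose
mean trace estimates the background under the cell.  The processing order
is enforced by state flags: neuropil subtraction → bleach correction →
Δf/f → band-pass.  Bleach correction fits a·exp(−t/τ) + c — the offset c
is included because a camera baseline does not decay to zero — and
subtracts only the exponential component; a non-convergent fit falls back
to linear detrending with a warning.  f₀ is the raw trace minimum (a
percentile-f₀ option exists but is off by default), so Δf/f requires a
positive minimum and double application is rejected.  The band-pass is a
zero-phase 4th-order Butterworth at [0.05, 0.8] Hz; any frame rate above
1.6 Hz (in practice 4, 6 or 16 Hz) passes.  Stacks are assumed registered;
a frame-to-frame correlation check warns when residual motion is likely.

## What the synthetic validation shows — and does not

Passing parameter recovery on the preset cohorts shows that the chain of
estimators is unbiased (within stated tolerances) for signals with the
study's structure: a single common oscillator, pulse-train envelopes,
stationary noise, stepwise light effects.  Real recordings add slow drift,
non-stationary carrier statistics, inter-channel crosstalk, movement/
perfusion artifacts, and rhythms that wax and wane; none of these are
emulated, so recovery here bounds estimator error, not robustness to every
recording pathology.  Problem sizes were chosen to exercise the estimators
at the study's own scales: cohorts of 12–16 experiments with two trials
each, 180 s drug trials at 10 kHz, 200-replicate calibrations at 2,000
bootstrap iterations, and 100-seed calcium classification runs.

## Interfaces

Recordings are read from delimited text or NPZ containers with a JSON
sidecar manifest (channel roles, events, group label); an adapter for Axon
binary files can plug into the same reader interface but is not bundled.
Envelopes, burst tables and summaries are written as delimited text/CSV
with JSON headers; calcium stacks as multi-page TIFF; ground truth as JSON.
The `locorhythm` CLI wraps each stage and a manifest-driven `run` verb
writes a `summary.json` with provenance (parameters, seeds, version).
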