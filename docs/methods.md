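# Methods

This note documents the models, conventions, and numerical choices behind
`sonoresponse`. It covers four pieces: acoustic dosimetry of burst-pulse
trains, dF/F0 quantification of calcium transients, the jitter-surrogate
null test for stimulus-locked multiunit activity, and the synthetic-data
generators used to validate all of the above.

## Dosimetry

A stimulus is a rectangular burst-pulse train: a carrier (typically 1 MHz)
gated at a pulse repetition frequency (PRF) with duty cycle `d` for a
duration `T`. Derived quantities:

- burst count `N = T * PRF`, required to be integral (tolerance 1e-9) —
  a train cannot contain a fractional burst;
- `I_SPPA = I_SPTA / d` for rectangular gating, where `I_SPTA` is the
  spatial-peak temporal-average intensity (W/cm^2);
- per-stimulus energy `E = I_SPTA * A * T` (J), with `A` the radiating
  area in cm^2. `I_SPTA` already averages over the gating, so no further
  duty factor enters;
- adiabatic bath temperature rise `dT = E / (V * rho * c)`, an upper
  bound that assumes the bath absorbs all acoustic energy with no loss.

The thermal constants default to water (`rho` = 1 g/mL, `c` = 4.184
J/(g degC)); they are a reconstruction — the published bound is consistent
with these values when nothing is rounded before the final result — and
both are overridable in `ThermalContext`. Values are rounded (2
significant figures) only at presentation, never internally. The envelope
generator emits an idealized rectangle with no rise/fall ramping, matching
the unsmoothed stimulus waveforms the analysis targets; ramped envelopes
are out of scope for v1.

## Calcium quantification

Traces are per-ROI mean fluorescence sampled nominally at 1 Hz. For each
stimulus, `F0` is the mean over the 30 s immediately before onset and
`dF/F0 = (F - F0)/F0`. The response magnitude is the **plain sum** of
dF/F0 samples over the 10 s after onset (units AU at 1 Hz); a trapezoid
option exists but is off by default because the sum is the field's
convention for this assay. Peak dF/F0 over the same window is reported
alongside.

Conventions the source protocol leaves open, fixed here:

- all windows half-open `[start, stop)`, so each frame belongs to exactly
  one window;
- `F0` is recomputed per stimulus (repeated stimuli in one recording are
  each referenced to their local baseline);
- a baseline window truncated by the start of the recording is an error,
  not a silently shortened window; likewise a truncated response window;
- stimuli spaced closer than the response window are refused rather than
  split heuristically;
- group summaries (mean +/- SEM) are taken over *session means*: the
  experimental unit is one imaging session, not one cell, matching how
  replicate counts are reported in this assay. SEM of a single session is
  NaN, never 0.

Routine group testing (ANOVA/Dunnett) is deliberately left to standard
statistical packages; this library stops at the response table and the
session summary.

## Multiunit activity and PSTHs

Raw voltage (20 kHz nominal) is high-pass filtered with a zero-phase
4th-order Butterworth (default cutoff 300 Hz, forward-backward so spike
troughs are not skewed). Multiunit events are negative crossings of
`-k * sigma` with `sigma = median(|v|)/0.6745` (robust to the spikes
themselves), `k = 4` by default, a 1-ms dead time, and the trough time
reported. These detector constants are standard extracellular practice
rather than derived from the source recordings (whose extraction method
is unstated); every one is exposed as a parameter, and `sigma` can be
supplied explicitly when the noise level is known.

PSTHs use 100-ms bins over a window of 3 s before to 3 s after stimulus
onset (the window is chosen equal to the jitter half-range so the null
bands are computed on the same support), counts summed over the ~20
stimuli of a session. Binning is half-open with offsets exactly on an
edge going to the right bin; stimuli whose aligned window is truncated by
the recording edges are dropped with a logged warning, never zero-padded.
The bin count total is exactly the number of (spike, stimulus) pairs in
the aligned windows — an integer identity the tests assert.

## The jitter-surrogate null test

Each of `n_surrogates` (default 1000) null datasets displaces every spike
by an independent uniform draw on [-3, +3] s — per spike, not per trial —
which destroys sub-3-s stimulus locking while preserving slow rate
structure and the exact spike count. Surrogate PSTHs are built with the
observed session's stimuli and bin geometry (spikes jittered outside the
recording are kept and simply fall outside all windows; clipping or
wrapping would distort edge-bin rates).

- Pointwise bands: per-bin empirical 2.5/97.5 percentiles (nearest-rank,
  type-1 quantiles — fixed so that band values are always realized counts).
- Global bands: the 95th percentile of per-surrogate *maxima* over all
  bins of the +/-3 s window (upper), 5th percentile of minima (lower).
  Since at most 5% of null draws exceed the upper global band *anywhere*,
  the familywise error over bins is controlled.
- Decision: a session is *activated* if any bin with left edge in
  [0, 1 s) after onset is strictly above the upper global band,
  *suppressed* if strictly below the lower one; activation is checked
  first (a session crossing both is reported as activated, with the
  earliest crossing bin).

Two genuinely open choices and how they were fixed:

1. **Global-band support.** The bands are computed from extrema over the
   full +/-3 s window while the decision inspects only the first second.
   This is the conservative reading (the alternative — extrema over the
   decision bins only — yields a larger type-I rate); the support is a
   parameter of the band computation via the PSTH geometry. Consequence,
   measured on null simulations: the realized type-I rate (both
   directions) is about 0.012 rather than the nominal ~0.10 that
   10-of-60-bin extrema would give. This is intrinsic to using full-window
   extrema with a sub-window decision and is documented rather than tuned
   away.
2. **Surrogate RNG.** Streams are keyed by (seed, surrogate index)
   through a `SeedSequence` spawn key, so surrogate i is bit-reproducible
   in isolation, independent of chunking or execution order. The
   vectorized band computation enumerates (spike, stimulus) pairs within
   jitter reach once and re-bins shifted offsets per surrogate; a spike
   near two stimuli keeps a single shared shift, exactly as if the whole
   train were jittered (asserted against the one-surrogate reference
   implementation in the tests).

The condition-level comparison is a Pearson chi-square on the 2x2
significant-by-condition table, without continuity correction by default
(Yates available via a flag); tables with a zero marginal are refused.

## Synthetic data

The generators define the conditions under which the pipeline is
validated; their defaults are fixed once and are not test-tuned.

**Calcium.** `F_i(t) = B_i (1 + s_i(t)) (1 + eps)`, with per-ROI baseline
`B_i` lognormal around 100 counts (sigma 0.2), `eps` iid Gaussian with sd
0.05 (shot-noise scale typical of widefield imaging), and `s_i` summing
unit-peak double-exponential kernels
`(e^{-t/tau_d} - e^{-t/tau_r})` (rise 1 s, decay 4 s, GCaMP6s-like at
room temperature). Evoked events hit responders only (80% of ROIs) with
per-ROI lognormal amplitude around peak dF/F0 = 1.5 (sigma 0.25);
spontaneous network events occur at 0.01 Hz, shared across the population
with 50% per-ROI participation, emulating synchronized culture-wide
oscillations and stressing the AUC statistic. A drug condition scales the
evoked amplitude multiplicatively (`condition_scale = 0` is full
blockade). Because the kernel is normalized to unit peak, "amplitude" is
directly the peak dF/F0, which is what the recovery tests compare. What
this generator does **not** emulate: photobleaching drift, motion,
neuropil contamination, and indicator saturation — so passing recovery
tests show the windowed statistics are correct, not that they are robust
to those artifacts.

**Spikes.** Stimulus times have uniform ISIs on [10, 20] s (20 stimuli);
spikes come from an inhomogeneous Poisson process by thinning, with rate
`baseline * (1 + (gain - 1) * 1[t - last stim in (latency, latency +
duration)])` — baseline 20 Hz, latency 0.1 s (the delayed onset expected
when a mechanosensitive conductance must first depolarize the network),
duration 0.5 s. Modulation is multiplicative so a drug factor composes as
a scale on `(gain - 1)`; `condition_gain_scale = 0` returns the session
to the null. Real multiunit trains have refractoriness, bursting, and
non-stationary baselines that this generator omits; the jitter test's
calibration on these sessions therefore demonstrates correctness of the
machinery under its own null, not robustness to slow non-stationarity
(which the jitter method is designed to tolerate but which is not
simulated here).

**Voltage.** Gaussian noise plus a stereotyped ~1.5-ms biphasic waveform
(sharp trough, slower overshoot) at each spike time, trough depth in
noise-sigma units (default 10).

## Problem sizes and numerics

Operating characteristics are measured on: 2000 null sessions at 250
surrogates each for type-I calibration, pointwise-vs-global inflation,
and (first 500 sessions) pooled band coverage; 100 sessions at the full
1000-surrogate default for power at gain 3; 60 ROIs for calcium recovery.
2000 replicates hold the standard error of the estimated null fraction to
~0.0025 so the estimate is dominated by the true rate, not by replicate
noise; 250 surrogates still resolve the 2.5th percentile with rank 7 and
were verified (1200-session pilot) to give the same realized type-I rate
as 1000. Degenerate inputs fail loudly: empty groups, zero marginals,
flat traces, truncated windows, and non-integral bin geometry all raise
typed errors rather than returning silently adjusted results.

## Known limitations

- The detector is threshold-based multiunit extraction only; no spike
  sorting, artifact rejection, or LFP analysis.
- The calcium module starts from per-ROI traces; segmentation and motion
  correction are upstream of this package.
- The thermal bound is adiabatic and therefore deliberately pessimistic.
- Acoustic field simulation (pressure maps, cavitation thresholds) is out
  of scope; intensity values are treated as calibrated inputs.
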