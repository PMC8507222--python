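# Methods

This note records the models, parameter choices and numerical conventions
behind the pipeline, and what the synthetic benchmark does and does not
establish about real recordings.

## Signal model and preprocessing

A recording is a channels × samples voltage matrix with a sampling rate
(nominally 60 electrodes at 25 kHz; the bundled analyses run a reduced
8-channel, 60 s, 5 kHz configuration, which preserves every algorithmic
property while keeping the full battery fast on one CPU).  Three conditioning
stages precede analysis:

1. **Savitzky–Golay smoothing** (order 2, 9-point window).  An 8-point window
   is not admissible for a symmetric SG kernel, so the nearest valid odd
   window is used; the window is a parameter.  SG reproduces polynomials up
   to the fit order exactly and shrinks broadband noise variance by the
   squared kernel norm (≈ 0.33 for 9/2).
2. **Spike band-pass**, 300–2500 Hz, linear-phase FIR (Hamming design,
   transition half the low edge, ≥ 50 dB stopband) applied by centred
   convolution — exactly zero phase, so spike times are never shifted.  At
   sampling rates where 2500 Hz reaches Nyquist, the upper edge is clamped to
   0.45·fs.
3. **LFP decimation** to 1000 Hz.  The anti-alias FIR preserves ≤ 400 Hz
   within 1 dB and places its stopband at the target Nyquist; integer
   decimation keeps sample alignment, other ratios use polyphase resampling.

All filters are linear and zero-phase; property tests assert both.

## Spike, burst and activity rules

Per electrode, the detection baseline is the mean and SD of the first 30 s of
the band-passed trace.  Events are local extrema of |x − mean| above 4 SD.
Both polarities trigger: extracellular spikes are negative-dominant but the
rule is symmetric in deviation.  The detector's default dead-time is 1 ms;
the assembled pipeline uses 2 ms because the 300 Hz band edge rings for about
2 ms around each waveform at amplitudes that can re-cross threshold, and
multi-unit events closer than that are not separable anyway.  A constant
(zero-SD) electrode yields an empty, flagged train rather than an error.

An electrode is **active** when it fires strictly more than 12 spikes per
minute; only active electrodes enter organoid-level averages.  A **burst** is
any group of ≥ 4 spikes within 100 ms.  Implementation: every window anchored
at a spike is tested (a qualifying window can always be slid left onto a
spike), overlapping qualifying windows merge, and the burst interval spans
first to last member spike.  This merge convention prevents one long
discharge from being counted repeatedly; its consequence — checked by
property tests — is that the monotone quantity under parameter changes is
the number of burst-member spikes, not the burst count (a laxer minimum
count can bridge two bursts into one).

ISI CV uses the sample SD over successive inter-spike intervals and is
flagged undefined below 3 spikes.

## Connectivity and periodicity

Spike-count correlation uses 50 ms bins (a burst-scale co-activation window;
exposed as a parameter) over a one-minute analysis window placed uniformly at
random.  Electrode pairs with Pearson r strictly above 0.5 are connected;
"percent connected" is the share of active electrodes with at least one edge
and "weight" the mean edge coefficient.  Zero-variance channels yield flagged
NaN entries and no edges.  Overlapping-burst connectivity joins two
electrodes when more than 25 % of either electrode's bursts intersect a burst
on the other (the threshold is a parameter; no canonical value exists).

The network spiking percentage is the fraction of active electrodes firing
per 100 ms bin.  Periodicity is sought in lags 0.5–30 s (frequencies
0.033–2 Hz): the lag-0-normalized autocorrelation's highest local maximum,
and the Welch periodogram's **lowest** suprathreshold local maximum.  The
Welch choice is deliberate: a periodic pulse process puts nearly equal power
at every harmonic, so the spectrum's global maximum lands on an arbitrary
harmonic while the fundamental is the lowest suprathreshold peak; the
autocorrelation needs no such care because its biased taper makes the
fundamental lag the highest peak.  The peak frequency is refined by
parabolic interpolation on log power.  A peak is reported only when it
exceeds the mean + 1 SD of the statistic over the search band (z is a
parameter).

**Specificity caveat.**  The mean + 1 SD rule is intentionally liberal and
has essentially no null specificity: the maximum of a few hundred
autocorrelation (or periodogram) values exceeds the mean + 1 SD of those same
values with probability ≈ 1 − Φ(1)^k ≈ 1, so pure noise always yields a
"period".  The acceptance suite measures this directly (≈ 100 % detection on
white noise).  The rule is kept because it is the field convention this
pipeline reproduces; users needing a calibrated detector should raise
`z_thresh` (≈ 3.6 gives ~5 % false positives at these series lengths) or use
surrogate thresholds.

## Oscillatory power

The 1000 Hz LFP is decomposed by a synchrosqueezed continuous wavelet
transform: analytic Morlet (μ = 6), 32 voices/octave over 0.5–450 Hz
(16 voices in the bulk pipeline — band assignment depends on the reassigned
instantaneous frequency, not the grid, so the coarser grid changes band
power by < 1 % while halving cost).  Coefficients are reassigned to their
phase-transform frequency ω(a,b) = Im[∂ᵦW/W]/2π, and a band's signal is the
one-sided Morlet inverse restricted to coefficients whose reassigned
frequency falls inside the band:

x_band(b) = (2/C_ψ) · Re Σ_{a: ω∈band} W(a,b) a^{−3/2} Δa,  C_ψ = ∫ψ̂(ξ)dξ/ξ.

On single tones this reconstruction recovers > 99.9 % of variance in the
correct band and < 0.01 % elsewhere, and agrees with a zero-phase FIR
band-pass to well under 10 % variance of difference (cross-method test).

Relative band power integrates the Welch PSD (2000 ms window, 1000 ms
overlap) of each band signal over that band's edges and normalizes across
the six bands, so the six fractions sum to one; the inter-band gaps (4–5,
8–9, 13–14, 32–33, 80–100 Hz) are deliberately unassigned.  Delta's lower
edge is 0.5 Hz to exclude DC drift.  All-zero channels are flagged.

Band-power connectivity computes, per electrode, one relative-power value
per 5 s window — by direct PSD integration over band edges, since a
per-window reassigned transform would add cost without changing the windowed
power estimate — and connects electrodes whose Pearson coefficient exceeds
the median + 1 SD of the coefficient distribution.

## Phase-amplitude coupling

Phase and envelope come from the analytic (Hilbert) signal of zero-phase FIR
band-passed traces (≈ 3 cycles of the low band edge of filter length).  The
modulation index bins phase into N = 18 bins of 20°, averages the envelope
per bin, normalizes to a distribution P and reports
MI = (log N − H(P))/log N ∈ [0, 1]: 0 for phase-uniform envelopes, 1 for a
single-bin concentration.  Empty bins get zero mass and are flagged (with
≥ 60 s at 1000 Hz they indicate degenerate phase coverage).  MI is invariant
to envelope scaling and to phase rotation (exactly, for rotations by whole
bins); because MI divides the KL divergence by log N, the bin-robust
quantity is D_KL = MI·log N, and MI itself scales as 1/log N in the bin
count — the tests pin both behaviours.  The standard panel couples
delta/theta phase to lower/upper gamma amplitude, averaged over active
electrodes.

## The simulator

Each channel is Gaussian noise (5 µV SD) plus three additive components with
exact bookkeeping:

- **Spikes**: a biphasic, negative-dominant ~2 ms template (peak magnitude =
  configured amplitude, default 50 µV = 10× noise SD) injected at tonic
  Poisson times (1 Hz), at Poisson burst onsets (renewal clusters of 6
  spikes, 15 ms apart), and at periodic **network events** (default every
  5 s) that recruit a fixed random subset of ⌈participation·n⌉ channels with
  ≤ 10 ms jitter.  A 2 ms absolute refractory is enforced on the merged
  train, which keeps ±1 ms spike matching well-posed.  The subset is fixed
  per recording so that ground-truth connected pairs are exact.
- **Oscillations**: band-centre sinusoids with slow (τ ≈ 2 s) random
  amplitude drift, making band-power ground truth analytic; optionally the
  drift realization is shared across the network subset to create a known
  band-power-connectivity component.
- **Coupling**: with depth m, the amplitude band's envelope is multiplied by
  (1 + m cos φ)/(1 + m), φ being the phase band's carrier phase.

Presets: `healthy` (4 independent bursts/min, 90 % network participation,
5 µV delta, coupling depth 0.2) vs `mutant` (2 bursts/min, 50 %
participation, 12 µV delta, depth 0.7).  The magnitudes are this package's
choices, sized so that network events dominate burst activity (as in a
strongly synchronized culture) and each phenotype contrast exceeds twice the
between-organoid sampling SD; no quantitative effect sizes exist to copy, so
these must not be read as measured biology.

What the simulator does *not* emulate: electrode geometry and volume
conduction, spike waveform diversity and sorting ambiguity, non-stationary
development over minutes, 50/60 Hz line noise, movement or perfusion
artifacts, and broadband 1/f background (oscillations are narrow-band by
construction).  Passing tests therefore demonstrate algorithmic correctness
and recovery under the stated generative model, not robustness to every
property of tissue data.

## Statistics

Organoid values are arithmetic means over active electrodes (network-level
quantities are computed once per recording).  Z-scores use the sample
(n − 1) SD; zero-variance metrics yield flagged zero rows.  Group
comparisons run a Kruskal–Wallis omnibus plus reference-vs-group two-sided
Mann–Whitney tests with Holm correction — a rank-based many-to-one scheme
standing in for figure-style "ANOVA on ranks with Dunnett's correction",
which has no exact nonparametric analogue.  The type-I error of this scheme
is verified at ≈ 5 % on simulated nulls and its power > 90 % for 3 SD shifts
at n = 10.

## Problem sizes

The bundled analyses and the acceptance script use 8 channels × 60 s at
5 kHz (spike stage) / 1 kHz (LFP stage) and cohorts of 10 organoids per
phenotype — large enough that every detector operates in its intended regime
(≥ 1000 spikes/recording, 12 network events/minute, 60 power windows) while
the full battery completes in minutes on one CPU.  Scaling to 60 channels at
25 kHz changes only the I/O chunking, not the algorithms, and the io layer
is tested at that channel count.
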