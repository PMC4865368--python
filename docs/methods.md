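# Methods

This note documents the generative model behind `sacerr.synth`, the
estimation procedures the analysis modules implement, the numerical and
design choices that were genuinely open, and what the package's recovery
tests do and do not establish about real recordings.

## Task and data model

A session is a set of delayed-saccade trials: the animal fixates, two targets
appear at ±10° on the horizontal meridian, a spatial cue selects one, and the
fixation point's offset is the go signal. Each trial carries 1 kHz
horizontal/vertical eye position (degrees), per-neuron spike times, and event
times, all in milliseconds from trial start. Analysis windows are half-open
`[a, b)`; alignment re-expresses times relative to a named event. Positive x
is rightward; for pooling, left-direction trials are sign-flipped into
"motor coordinates" so the (preferred) target maps to +10°.

Fixed trial timeline in generated sessions: fixation at 0 ms, targets at
500 ms, cue 900–1100 ms, fixation-point offset at 1500 ms, trial length
2800 ms. Saccade latency ~ N(200, 40) ms clipped to [80, 420]; duration
~ U(25, 60) ms, drawn independently of amplitude (no main-sequence coupling —
see Limitations).

## Synthetic saccades

The velocity profile is a raised cosine: displacement
`x(u) = A·(u − sin(2πu)/2π)`, `u = (t − onset)/duration`, giving peak speed
`2A/duration` (≥ 330°/s for a 10° saccade at the longest allowed duration,
comfortably above the 30°/s detection threshold). Horizontal end positions
are drawn from N(9.6615°, 0.4894°) in motor coordinates — the narrow
end-point distribution the task produces in trained animals — with
independent N(0, 0.15°) vertical jitter. A zero-mean exponential settling
drift (amplitude 0.02°, random sign) and white position noise (SD 0.004°) are
added. Corrective saccades are raised-cosine movements toward the target
(amplitude floored at 0.3° so that a flagged correction is kinematically
detectable) launched N(154, 25) ms after the primary saccade's end.

## Firing-rate model

All rates are in spikes/s; trains are inhomogeneous Poisson, sampled by
thinning under an explicit per-trial rate bound (the analytic maximum of the
profile plus margin). Time rescaling is used only as an independent sampling
oracle in the tests.

**PPS neurons** — baseline 8 until 200 ms before saccade onset, then an
accelerating ramp `u^1.5` that peaks *at* the neuron's decay point
(`saccade end + decay_ms`), followed by exponential decay (τ = 60 ms) back
toward baseline. The profile never depends on the realized end position. In
the preferred direction an error term
`error_gain · |error| · g · bump(t − saccade_end)` is added, where `bump` is
1 on the 150–350 ms post-saccadic epoch with 50 ms raised-cosine edges and
`g ~ Gamma(shape 4, mean 1)` is a per-trial error-signal strength. The
ramp-to-peak shape matters: with a flat plateau between saccade end and the
decay onset, the minimum-residual start of the exponential-fit procedure
(below) is unidentifiable under spiking noise; with the peak at the change
point, the density peak itself marks it, which is also how the neurons these
profiles emulate are described (rise to a peak ~100 ms after the saccade,
then decay).

**LPS neurons** — baseline until `saccade end + rise_ms`, then a saturating
rise (τ = 25 ms) to `baseline + direction_gain + position_gain · x_end`
(motor coordinates). τ = 25 ms is a compromise forced by identifiability: a
near-step rise is absorbed by the growing exponential branch from any start
(the fit start becomes meaningless), while a much slower rise fails to
saturate inside the ±250 ms fit window for late-onset neurons, leaving a
convex segment with the same degeneracy.

**Null neurons** — homogeneous Poisson at a jittered baseline.

Null-direction responses are 10% of the preferred-direction modulation, so
direction-selectivity criteria pass with realistic margins.

### Decay/rise latency distributions

Per-neuron decay (PPS) and rise (LPS) latencies are drawn from the parent
normal whose truncation below 35 ms has exactly the configured population
moments (74.8 ± 33.1 ms decay, 70.9 ± 31.3 ms rise). The 35 ms bound is the
classification rule itself: the empirical populations these moments describe
were selected by that rule, so the reported moments are post-selection
moments, and a generator that feeds the untruncated normal through the
classifier would both shift the recovered means and create neurons that
contradict their own labels. Draws are stratified (neuron *j* of *n* samples
quantile `(j+u)/n`), so small populations represent the configured
distribution; the cost is that adding neurons re-slots the quantiles.

### The corrective-saccade decision

The decision to make a secondary saccade is an *activity readout*: the
trial's pooled PPS post-subtraction rate (neurons preferring the trial's
direction), minus its analytic zero-error expectation, is converted to
degrees of error-equivalent signal `ŝ` and passed through
`P = clip(0.05 + 0.30·ŝ, 0, 1)`. Averaged over spiking noise this reduces to
`P ≈ base + slope·|error|` (the readout noise plus clipping lifts the
effective floor), but trial by trial the decision covaries with the very
signal the analysis measures — which is the comparator hypothesis: the error
signal, not the raw error, drives the correction. Defaults were calibrated
once so the induced overall rate (~0.28–0.32) brackets the ~0.25 rate typical
of this task. With no PPS neurons or zero error gain the generator falls
back to the literal linear-in-error law. Consequence: the secondary-saccade
flag depends on the PPS population, so adding PPS neurons can change flags
(behavioral kinematics otherwise use per-trial RNG streams independent of
the neuron count).

### The comparator-consistent error gain

`pps_error_gain` has no empirical anchor and defaults to the value that makes
the generator internally consistent with the subtraction model *as measured*:
the normalized LPS position slope observable in the 25–125 ms readout window
(attenuated by the rise latency distribution and τ, a factor ≈ 0.36 computed
by quadrature) must equal the normalized PPS post-subtraction error slope
(bump window mean 0.75). Hence
`error_gain = position_gain · lps_attenuation / bump_attenuation ≈ 2.4
(spikes/s)/deg` at the defaults. Without this coupling the predicted
|LPS − PPS| curve and the observed post-subtraction curve would differ by an
arbitrary scale and the subtraction-model comparison would be vacuous.

### Random streams

Every randomness source derives from one integer seed. Per-purpose streams
(behavior, neuron parameters, spikes, decisions, trace noise) are seeded by
SHA-256 hashes of `(seed, namespace, indices...)`. The obvious alternative —
`numpy.random.SeedSequence(entropy=seed, spawn_key=key)` — produced
measurable cross-stream correlations for small integer seeds (spike counts
tracking the behavioral latency draws at the +4σ level over a few hundred
trials), which is far outside what independent streams may do; the hashed
construction removed it. Identical config ⇒ bit-identical session, including
the HDF5 container bytes (datasets are written with `track_times=False`).

## Saccade detection

Eye speed is the magnitude of the centrally-differenced position after a
5 ms boxcar (both configurable; the detection thresholds come from the
analysis definition, the differentiator does not). The primary saccade starts
at the first sample after the go signal (search window 600 ms) with speed
> 30°/s; the peak is the maximum until speed first returns below 30°/s; the
offset is the first sample after the peak with speed < 10% of the peak. The
end point is the mean eye position over the 20 ms after the offset. Because
the 10% crossing happens at a fixed phase of the raised-cosine profile,
detected offsets in synthetic data sit ~3–6 ms before the nominal profile
end; end-point positions are recovered to < 0.01°.

Trial inclusion: duration within [10, 100] ms (inclusive), end point within a
5° window centered on the target (square window `|Δx|,|Δy| ≤ 2.5°` by
default; circular optional), amplitude strictly > 4°, latency strictly
< 500 ms. Secondary saccades: onset threshold 8°/s, duration > 5 ms,
amplitude > 0.2°, onset ≥ 100 ms after the primary offset; all qualifying
events count regardless of direction. Template-matching criteria sometimes
mentioned alongside velocity thresholds are not defined anywhere and are not
implemented. Both detectors are exactly equivalent to a plain sample-by-sample
threshold scan, and that equivalence is tested.

## Spike density and epochs

The density estimate is the classic Gaussian-kernel rate (σ = 5 ms — the
value the change-point procedure prescribes; population displays reuse it),
computed by binning spikes on the 1 ms grid and convolving with a discrete
Gaussian (zero padding; mass is exact, spike times are effectively rounded to
the grid). Epoch rates are raw counts over half-open aligned windows divided
by window length — not density integrals — for single-trial robustness.

Baseline windows follow their uses: classification compares against
[0, 500) ms after fixation onset; normalization divides by the mean rate in
[100, 500) ms after fixation-point onset, floored at 1 spike/s to keep
near-silent cells finite (normalized activity is then scale-invariant when
the baseline is above the floor). Population averages report pointwise
normal-approximation 95% CIs.

## Change-point estimation

For each neuron the trial-averaged density (preferred direction, σ = 5 ms)
on [−250, +250) ms around saccade completion (onset alignment [−200, +300)
is also supported) is scanned with a 20 ms moving window stepped at 1 ms:

1. *Decay*: the peak bin is the maximal moving mean (ties → latest bin; the
   peak point is the last maximal raw sample inside it). The end point is the
   lowest post-peak bin. The fluctuation period runs from the peak to the
   first bin below `max(peak − 2·STE, 0.8·peak)`, refined to the first raw
   sample below the bound inside that bin. An exponential
   `y = A1·exp((x − x₀)/A2) + A3` is fit from every 1 ms candidate start in
   the fluctuation period to the end point; the start of the
   minimum-mean-squared-residual fit is the decay time.
2. *Rise*: mirror procedure — lowest pre-peak bin, fluctuation period up to
   the last pre-peak bin below `max(trough, baseline) + 2·STE`, fits run from
   each candidate to the peak.

Numerical choices: for fixed A2 the model is linear in (A1, A3), so fits
profile A2 over signed log grids with exact linear solves plus bounded 1-D
refinement (positive growth rates are floored at span/40 to keep the basis
finite). Candidate-selection fits are restricted to the decelerating branch
(A2 < 0): the growing branch can push its entire change to the end of the
segment, absorbing any flat lead-in, which makes the fitted start
meaningless as a change point. Residual ties (relative 10⁻⁹) break to the
earliest start so noiseless planted transitions — where every start at or
after the truth fits exactly — are recovered exactly. "2 STE" is the
across-trial standard error of the 20 ms bin mean; for the rise bound it is
the median bin-SE over the whole pre-peak segment, because a bin-local SE
evaluated inside a deep trough (few spikes) underestimates the trace's
sampling noise. A monotone or flat trace returns a structured
"no change point" result.

Operating characteristics at the defaults (60 trials/neuron, Poisson noise):
decay estimates run ~+5…+9 ms late (the selected start tracks the 2-STE bound
crossing, which sits a τ·log factor after the true corner), rise estimates
~2–4 ms early; per-neuron RMSE ≈ 18 ms (decay) and ≈ 8–10 ms (rise), within
the ±10 ms population-mean recovery tolerance the tests enforce.

The **middle point of change** of a population trace — the time the trace
crosses halfway between its pre-change plateau and post-change extreme
(linear interpolation) — summarizes timing at the population level; on
default populations the LPS rise midpoint precedes the PPS decay midpoint,
the temporal prerequisite of the comparator.

## Classification

Preferred direction: the direction with the larger mean rate over the union
of the pre-saccadic ([−200, 0) re onset) and [0, 300) post-saccadic windows;
ties break rightward; ≥ 10 included trials per direction required.

PPS rules (all must pass): (1) pre-saccadic rate above baseline, paired
t-test p < 0.01; (2) ≥ 5 of 10 contiguous 20 ms bins tiling the pre-saccadic
interval above baseline at p < 0.05; (3) preferred above null pre-saccadic
rate, rank-sum p < 0.01; (4) estimated decay time > 35 ms after saccade end.

LPS rules: (1) no pre-saccadic elevation (paired t-test); (2) no elevation in
[−150, 0) re saccade end against baseline (signed-rank) or the null direction
(rank-sum); (3) one of the [0, 200) / [100, 300) post-saccadic windows above
both baseline and the null direction at p < 0.05 (the window with the larger
elevation wins); (4) ≥ 2 of 4 contiguous 50 ms bins tiling the *responsive*
window above baseline at p < 0.05; (5) estimated rise time > 35 ms.

Two interpretation choices deserve emphasis, both forced by
self-consistency: the "quiet" rules (LPS 1–2) are directional — they fail
only on a significant *elevation*, because a two-sided "not significantly
different" rejects ~5% of genuinely silent neurons per test by construction;
and the LPS-4 bins anchor on whichever rule-3 window carried the response,
because anchoring always at [0, 200) would make any rise later than ~140 ms
unclassifiable while the reported rise-latency spread requires such neurons
to exist. Test mapping: paired t-tests for trial-paired rate-vs-baseline
comparisons named as t-tests, Wilcoxon signed-rank where a Wilcoxon test is
named on paired data, rank-sum for independent trial sets. Labels are
mutually exclusive; in the pathological case that both rule sets pass the
neuron is labeled PPS and flagged. Every labeled neuron carries a statistic
and p per rule.

At the defaults (200-neuron population, 200 trials/direction) the classifier
recovers ≥ 95% of PPS and ~92% of LPS neurons with specificity 1.0 and no
PPS↔LPS confusion; the missed LPS neurons are the irreducible α-level
false-fails of the quiet rules plus latency draws within estimator noise of
the 35 ms bound.

## Comparator analysis

Per neuron, per included preferred-direction trial, epoch rates are
baseline-divided. The analysis pools (neuron, trial) pairs in motor
coordinates on a common end-position grid: 16 equal-width bins spanning
mean ± 3 SD of the end positions (outliers clip into the edge bins), merged
once at the *trial* level until every bin holds ≥ 5 trials, after which all
binned quantities share the frozen edges. Reference subtraction sets the bin
containing the target to zero. The subtraction model compares the observed
post-subtraction bin means with |LPS fit − PPS fit| evaluated on the bin
centers (count-weighted OLS lines of the reference-normalized LPS 25–125 ms
and PPS perisaccadic curves); agreement is the plain RMS over populated bins.
Piecewise hypometric/hypermetric regressions split at the target
eccentricity.

Single-trial correlations are Pearson r per neuron (≥ 30 trials; raw r, not
Fisher-z, with zero-variance neurons excluded and reported), and the
population-level test is a one-sample t-test of the per-neuron r values
against zero — the only coherent reading of a "paired" test applied to a set
of correlation coefficients. The sliding-window analysis computes the same
per-window (100 ms windows, 10 ms steps, spanning [0, 450] ms after saccade
end, stamped by midpoints).

**A calibration caveat that matters for synthetic data**: within one
generated session every neuron sees the same trials, so per-neuron r values
share any behavioral sampling fluke and the across-neuron t-test is
anti-conservative against them (real populations pool neurons from many
recording sessions). Null-calibration checks therefore pool neurons from
several independently generated sessions.

## Secondary-saccade analysis

Trials must pass the primary filters; secondary saccades of any direction
count, with the toward-target fraction reported descriptively. Probabilities
and activity are computed on the comparator's bin partition, re-merged to
≥ 30 trials per bin by default (≥ 150 in the large acceptance run) because an
empirical probability needs a real denominator — the activity analyses keep
the ≥ 5-trial merge. Per bin: P(secondary), mean post-subtraction activity,
the with/without-secondary activity split with rank-sum p, plus piecewise
probability-vs-position fits. The activity–probability correlation is
Pearson r across bins (≥ 4 bins required).

## Problem sizes used in the validation suite

Detector-oracle equivalence on 500 trials; change-point recovery on 89 PPS +
27 LPS neurons × 60 trials; classifier recovery on 100/60/40 neurons × 200
trials/direction; comparator dissociation on 55 PPS + 22 LPS × 400
trials/direction; secondary coupling on 12 PPS × 2000 trials/direction plus
100 replicates of 6 PPS × 150 trials/direction; generator fidelity on 4090
trials. These sizes mirror the populations the defaults describe while
keeping the full suite runnable in minutes.

## Limitations

* The generator realizes the comparator hypothesis *by construction* (the
  error term is injected into PPS rates, and the corrective decision reads it
  out). Recovery therefore validates the analysis chain — detection,
  estimation, classification, statistics — not the biological claim.
* No main-sequence amplitude–duration coupling, no microsaccades during
  fixation, no blinks or artifacts, no reward or licking signals; eye noise
  is white and small relative to coil recordings with heavier filtering.
* The exponential-fit change-point procedure has a small procedure-inherent
  late bias for decays (see above); population means inherit it.
* Rate profiles are piecewise-deterministic with Poisson variability only;
  real neurons show trial-to-trial rate covariations beyond the scalar
  error-signal gain modeled here.
* Single-session population statistics are anti-conservative against shared
  behavioral flukes, as noted; multi-session pooling is the remedy and is
  what the calibration checks use.
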