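# Methods

This note records the models, parameter choices and numerical conventions
behind `catrace`, including the places where the procedure admitted more
than one reasonable reading and which one the package takes.

Conventions used everywhere: time in seconds, frames 0-based, intervals
half-open `[start, end)`.  Frame `i` at frame rate `f` covers
`[i/f, (i+1)/f)` and belongs to the behavioral bout containing its start
time.  All randomness flows from integer seeds through
`numpy.random.Generator`; per-neuron substreams are derived with
`SeedSequence((seed, neuron_index))`, so results are independent of
processing order and bit-reproducible.

## Trace processing

**Sliding baseline.**  F₀ for each neuron is a quantile over a centered
window of 500 frames (≈ 50 s at 10 Hz), truncated — not padded — at the
session edges, with linear interpolation between order statistics.  The
quantile adapts to how active the neuron is: a rolling-median pre-pass
gives a provisional baseline; the activity fraction is the fraction of
frames exceeding it by 2 robust SDs (1.4826 × MAD of the residuals); and
the final quantile is `clamp(0.50 − activity_fraction, 0.10, 0.50)`.
Silent neurons therefore use the running median, busy neurons slide toward
the 10th percentile so frequent transients do not inflate F₀.  The
mapping is one concrete, monotone realization of an "activity-dependent
quantile between the 10th percentile and the median"; the pre-pass
multiplier and the linear form are package choices.  A non-positive F₀
anywhere aborts with an error: it signals raw units for which ΔF/F is
meaningless.

**ΔF/F and standardization.**  ΔF/F = (F − F₀)/F₀ elementwise;
standardization subtracts the per-neuron median and divides by the sample
SD (ddof = 1 throughout — the convention is a package choice), leaving
traces in SD units with median 0.

**Deconvolution stand-in.**  Spike-rate inference is a first-order inverse
filter against the indicator's causal exponential kernel:
`y(t) = x(t) − λ·x(t−1)` with `λ = 2^(−1/(t_half·f))`, half-wave
rectified.  Re-convolving the unrectified output with the kernel
reconstructs the input exactly (machine precision), which the tests
assert.  The function is deliberately pluggable — any callable with the
same signature (e.g. a learned model) can replace it in the pipeline.

**Activity-masked z-scoring.**  Baseline mean/SD are estimated only from
frames lacking Ca²⁺ activity: iterate (≤ 5 rounds) masking frames above
mean + 3 SD of the currently unmasked frames until stable.  The 3 SD
masking threshold mirrors the downstream event-amplitude criterion.

## Event detection

A candidate envelope is a maximal run of frames with the trace at or above
the 0.5 SD baseline level.  It becomes an event iff its peak reaches 3 SD
and it lasts at least `t_half·log₂(A/A₀)` with `A₀ = 0.5` and
`t_half = 0.2 s` — the decay time from the peak back to baseline at
GCaMP6f kinetics, so anything decaying faster than the indicator is
rejected as noise.  Two numerical points matter:

* **Duration is measured between interpolated threshold crossings**, not
  by counting suprathreshold samples.  An ideal indicator transient meets
  the duration bound with near equality, and sample counting is biased low
  by up to one frame at each edge — enough to reject a sizable share of
  genuine events at realistic noise.  Linear interpolation of the up- and
  down-crossing is the unbiased discrete estimator of time above
  baseline.
* **Duration spans onset→offset** of the envelope (the more inclusive of
  the two readings of "before returning to baseline"; peak→offset would
  be stricter and is not used).

Multi-peaked envelopes are split with `scipy.signal.find_peaks`
(prominence ≥ 2.5 SD, spacing ≥ 1 s) on the envelope padded below its
floor, so edge maxima count and prominences are measured against the
envelope interior.  scipy applies the distance filter (tallest peak wins,
earlier peak on ties) before the prominence filter; the tests pin this
semantics against an independent brute-force enumerator.  The envelope is
cut at the trace minimum between adjacent retained peaks (earliest frame
on ties), and each retained peak is the summit of its event — a taller
local maximum suppressed by the distance rule does not re-emerge as a
sub-event peak.  Split sub-events are not re-gated on amplitude or
duration; the parent envelope already passed.

**AUC/sec** is the rectangle-rule integral of `max(trace, 0)` over each
event's `[onset, offset)`, summed and divided by the recording duration —
rectangle rather than trapezoid to match discrete per-frame semantics.
Neurons with no events score 0.

## Population ranking and composition

Neurons are sorted ascending by `(AUC/sec, neuron_id)` and the top
`ceil(0.10·n)` labeled active; the id tie-break makes the split
deterministic.  The ranking pools all neurons given in one run (the
per-group vs per-animal scope of the 10% cut is not fixed by the
procedure; per-run pooling is the default and callers can subset).
Composition tables are tested with Pearson's χ² on the 2×2 counts without
continuity correction, df = 1.

## Freezing selectivity

The statistic is the mean trace value during freezing frames minus the
mean during all other frames, computed on the standardized trace by
default (configurable; which processed trace the original procedure used
is not stated).  The null permutes the order of behavioral bouts — each
keeps its state and exact length — preserving total occupancy and the
bout-length multiset exactly; this matches "epochs fixed in length" more
faithfully than a circular shift and is exact under exchangeability of
bout arrangement.  The p-value uses the add-one estimator
`p = (1 + #{|null| ≥ |obs|})/(n_iter + 1)` (never zero), and direction
comes from the sign of the observed difference: p < α with a positive
difference → freezing neuron, negative → non-freezing, else
nonselective.  With a two-sided magnitude comparison each direction has
type-I error ≈ α/2; whether the original rule was one- or two-sided is
ambiguous, and this choice is the conservative one.  Internally the null
is computed by permuting the per-bout frame-count sequence and reading
segment sums off one cumulative sum — frame-for-frame identical to
rebuilding shuffled tracks (asserted in tests) but O(bouts) per
iteration.

An important property verified in the tests: neurons recorded in the same
session share one behavior track (and, in simulation, one drift phase),
so their selectivity calls are *correlated* — error-rate fractions only
concentrate at the nominal level when aggregated across independent
sessions.  The type-I suite therefore spreads its 1,000 null neurons over
10 independent 600 s sessions.

## Count ratios

Ratios (marker/DAPI, overlap/marker, …) are computed per slice and then
averaged per mouse — the per-mouse value is the mean of its slices, not
the ratio of pooled counts.  Slices with a zero denominator are excluded
from that mouse's average with a warning rather than failing the run.
`chance_overlap` supplies the independence baseline
(m₁/DAPI)·(m₂/DAPI) per slice.  Two-group comparisons are thin wrappers
over scipy (pooled-variance t, paired t, Mann–Whitney, Pearson); the
caller always names the test — no normality-gated automatic dispatch.

## Synthetic sessions

The generator emulates the statistical structure the analyses assume, not
pixel data:

* **Behavior**: alternating freezing/non-freezing bouts with exponential
  lengths, quantized to whole frames with a 2-frame floor.  The freezing
  and non-freezing means are `2·bout_mean_s·occ` and `2·bout_mean_s·(1−occ)`
  so the expected occupancy equals the target while the grand mean bout
  length stays at `bout_mean_s` (default 12 s — plausible for contextual
  fear tests; not calibrated to any particular dataset).  Tracks are
  resampled (≤ 100 draws) until realized occupancy is within ±10
  percentage points of target; exact 0 or 1 yields a single-bout session.
* **Events**: per neuron, a piecewise-constant-rate Poisson process
  (default 0.05 events/s, sparse DG-like firing); freezing-selective
  neurons multiply (non-freezing-selective divide) their rate by
  `modulation_factor` during freezing bouts; `modulation_factor = 1` is
  the behavioral null used for error-rate suites.
* **Fluorescence**: each event adds a unit-peak kernel with a 50 ms linear
  rise (the rise time is a package choice; only the decay half-life is
  indicator-constrained) and exponential decay, t½ = 200 ms.
  `F = baseline·(1 + drift)·(1 + Σ kernels) + N(0, noise_sd)` with a
  one-cycle-per-session sinusoidal drift of relative amplitude 0.1
  (default) and additive Gaussian noise, default SD 1.0 on a baseline of
  100 — i.e. 1% ΔF/F frame noise, typical of ROI-averaged somatic
  GCaMP6f.  Photon-shot scaling of the noise with brightness is *not*
  modeled.
* **Count tables**: per slice, DAPI nuclei fall multinomially into
  {mCherry only, cFOS only, both, neither} with
  `P(both) = p₁·p₂·enrichment`; enrichment 1 is chance-level overlap.

What passing tests on these sessions do **not** show: robustness to
motion artifacts, neuropil contamination, non-exponential indicator
kinetics, photobleaching trends faster than the drift model, or freezing
bout statistics of real mice (the paperless defaults above are
placeholders in that respect).

## Problem sizes and tolerances

Permutation suites run 1,000 iterations per neuron (p-resolution
1/1001, ample against α = 0.01); recovery uses one 200-neuron 600 s
session at 5× modulation; detection scoring uses 50 neurons with matching
tolerance ±2 frames; threshold bisections run to 0.01 SD.  These are the
smallest sizes at which the binomial noise of the measured fractions is
comfortably inside the margins being checked.  The brute-force baseline
oracle is exercised up to 2,000 frames.

## Known limitations

* The inverse-filter deconvolution is a linear stand-in; it does not
  denoise, so the default analysis stage for detection and selectivity is
  the standardized (not z-scored-deconvolved) trace.
* Split sub-events inherit no re-check of the amplitude/duration gates.
* The activity-dependent quantile mapping is one of several monotone
  realizations consistent with its verbal description.
* Mixed-effects structure across mice (slices within mouse, mice within
  group) is reduced to per-mouse means before testing.
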