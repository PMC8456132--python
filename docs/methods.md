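# Methods

## Data model

The unit of annotation is the **element**: one discrete sound bounded by
silence, recorded as an onset and an offset in seconds from the start of
its acoustic sample. A **sequence** is an ordered run of elements
attributed to one individual; rhythm statistics require at least three
elements (two inter-onset intervals), and shorter runs are carried
through reporting with statistics withheld rather than dropped. Elements
within a sequence must be strictly ordered and non-overlapping; both are
validated at construction with the offending pair named.

Sequence assembly follows the one-sequence-per-acoustic-sample regime by
default (`gap_threshold=None`): each annotation file is one sample and
its elements form one sequence. An onset-gap threshold can instead split
a file into several sequences; sequences are never assembled across
files, whose time axes are independent. Attribution of sequences to
individuals by signal-to-noise ratio is an audio-level judgement that
cannot be made from annotation tables and is out of scope here; the
tables are taken as already attributed.

All analysis operates on the **IOI sequence**, the consecutive onset
differences. IOIs include the element duration plus the following gap,
so they are insensitive to offset-annotation precision.

## Variability statistics

* **nPVI** = 100/(m−1) · Σ |dₖ − dₖ₊₁| / ((dₖ+dₖ₊₁)/2) over consecutive
  ordered IOI pairs — the standard linguistic normalized pairwise
  variability index. It is 0 iff all IOIs are equal, < 200 always,
  invariant under uniform time rescaling and under reversal of the IOI
  order, and for a two-valued alternation (a, b, a, b, …) equals
  200·|a−b|/(a+b) independent of length. Values below 30 are treated as
  a strong indicator of underlying isochrony; the mapping is asymmetric
  by design — high values are *inconclusive*, never "not isochronous",
  because long jittered isochronous sequences can score high.
* **C_V** = sd/mean of the IOIs. The sample standard deviation (m−1
  denominator) is the default: with the short sequences typical of field
  data the choice is material, and the sample form is conservative. The
  population variant is a one-argument toggle (`ddof=0`).
* **Histograms** pool IOIs across all sequences of one sound type and
  use Sturges' rule, k = ⌈log₂ n⌉ + 1 equal-width bins over [min, max]
  of the pooled IOIs, with per-bin percentages of the pooled count. When
  all IOIs are identical the range is degenerate; a single bin of
  machine-epsilon nominal width holds everything so count conservation
  still holds and is testable.

## Beat estimation

The **IOI beat** is 1/mean(IOIs): beats per second under the sequence's
average spacing.

The **Fourier beat** works on a binarized onset train: onsets are
re-referenced to the first onset and mapped to the nearest sample of a
regular grid, 20 Hz by default, bounding resolvable beats by the 10 Hz
Nyquist frequency. Nearest-sample rounding introduces at most half a
sample period of timing error (25 ms at 20 Hz); two onsets closer than
one sample period would collapse and raise an error advising a higher
rate rather than silently merging. The mean is removed so the 0 Hz
component of the 0/1 train does not dominate, the train is zero-padded
until the frequency grid is at least as fine as 0.01 Hz (matching the
two-decimal precision beats are conventionally reported at), and the
magnitude spectrum is searched in a window of (0.1, 10] Hz by default.

Two numerical choices matter here:

* **Harmonic ties.** A strictly isochronous comb places *equal*
  magnitude on every harmonic of its fundamental, so a bare argmax picks
  an arbitrary harmonic on leakage-level noise. Local spectral maxima
  within 2% (relative) of the global maximum therefore count as tied and
  the lowest-frequency tied peak is returned, preferring the fundamental.
  The margin is small enough not to disturb the induced-isochrony case,
  where the occupied-grid harmonic genuinely dominates the fundamental
  by ~20%.
* **Resolution.** Zero-padding only interpolates: the intrinsic
  resolution is ~1/(train duration), and trains shorter than ~1 s are
  flagged with a low-resolution warning. Recovery accuracy is assessed
  against the intrinsic step, exactness of noiseless worked cases
  against the 0.01 Hz grid step.

The default search window opens below the nominal 1–10 Hz band because
sequences with multi-second IOIs (common in fish) carry beats well below
1 Hz; the nominal band remains selectable per call or via config.

**Isochrony classification** matches each IOI exhaustively against
integer multiples k ≥ 1 of the beat period (checking the floor and
ceiling of IOI·f suffices). With every IOI within a relative tolerance
(default 15%) of some multiple: all k = 1 is *signal* isochrony (every
grid beat carries an element); any k ≥ 2 is *induced* isochrony (silent
beats); otherwise *none*. Two caveats are inherent to the definition and
documented rather than patched: (i) with relative tolerance t, multiples
k ≥ 1/(2t) always fit, so the label is only discriminating when the beat
period is comparable to the IOIs; (ii) the every-IOI rule makes the
signal label conservative — at 10% IOI jitter a long sequence will
usually contain one interval beyond 15% and be labelled *none* even
though its pool is plainly isochronous by nPVI and histogram shape. The
tolerance is a reported parameter, not a hidden constant.

## Recurrence matrices

D[i,j] = |dᵢ − dⱼ|, the one-dimensional Euclidean metric between scalar
IOIs — symmetric, zero-diagonal, triangle-inequality-satisfying, of side
equal to the IOI count. The display normalization to [0, 1] is strictly
per sequence (an all-zero matrix stays all-zero); scales are never shared
across sequences, so cross-sequence comparison uses the raw maximum
distance, which differs by orders of magnitude between isochronous and
arrhythmic sequences. Rendering maps 0 → white, 1 → black; no
recurrence-quantification statistics (determinism, laminarity) are
computed — the plot is descriptive.

## Synthetic archetypes

The generator draws IOIs, not onsets, so the distribution every
statistic operates on is explicit; onsets are their cumulative sum, and
offsets add a fixed element duration. Three archetypes:

* *isochronous*: IOI = 1/beat + N(0, jitter_rel/beat);
* *induced_isochronous*: IOIs cycle through `multiple_pattern`/beat
  (default [1, 4] at 2 Hz → 0.5 s / 2.0 s alternation) with the same
  jitter model, putting the IOI modes at integer multiples of the grid
  period;
* *random*: IOIs uniform over a broad range (default 5–180 s), matching
  the flat pooled histograms of arrhythmic callers; an exponential
  (Poisson-like) law is available as an option.

A jitter draw that would leave an IOI at or below the element duration
(overlap or non-positivity) is resampled; elements are never reordered.
Identical spec + seed reproduces the sequence exactly.

The **battery** emulates the sampling designs such pools are collected
under: 10 isochronous sequences (element counts ~ N(28, 7), truncated at
3) at a 0.4 Hz base beat with 10% jitter — multi-second IOIs and nPVI
medians in the low tens, as isochronous fish choruses show; 20
induced-isochronous sequences (~N(10, 4)) on a 2 Hz grid with the [1, 4]
pattern and 5% jitter; 10 random sequences (~N(5, 1)) with IOIs of tens
of seconds. What the generator does *not* emulate: detection misses and
false alarms, annotation jitter from manual selection, SNR-based
individual attribution, chorus overlap, or tempo drift
(accelerando/ritardando). Passing tests therefore demonstrate that the
*estimators* behave correctly under known timing structure, not that
field annotations are error-free.

## Pool report and the arrhythmic flag

Beats are withheld for pools where no underlying rhythm can plausibly be
assumed. The decision is a documented descriptive heuristic on the
pooled IOI distribution, with every threshold exposed in
`AnalysisConfig`:

1. take the top Sturges bin, refine its centre to the median of IOIs
   within a ±25% relative window, and measure the mode's mass share;
2. *unimodal* if the share ≥ 0.75;
3. otherwise find the best bin outside that window, refine it the same
   way; *multimodal-with-multiples* if the two modes jointly hold ≥ 0.75
   and their centres sit at a near-integer ratio ≥ 2 (tolerance 25% of
   the integer) — the silent-beat signature;
4. otherwise *broad*, which flags the pool arrhythmic and skips beats
   unless `force_beats` is set.

The pool report also lists the mode centres and shares, the ratio, and
medians/ranges of nPVI, C_V and both beats, all labelled descriptive
aids: no modality hypothesis test (dip test etc.) is performed, matching
the visual-inspection practice the workflow encodes. Every summary
number is recomputable by calling the underlying module function on the
same inputs; the report layer does no arithmetic of its own.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on generated data:
pools of 10–20 sequences with 5–30 elements, parameter-recovery grids
over 0.3–8 Hz, and oracle cross-checks on 1000 random short IOI vectors
— sizes chosen to exercise every code path at interactive runtimes while
matching the sequence lengths the method is designed for. All randomness
flows through explicit integer seeds (numpy `default_rng`); identical
inputs and configuration produce byte-identical output artifacts.

## Known limitations

* Spectral peak magnitude is the only "fit" criterion; no separate
  goodness-of-fit statistic ranks candidate beats, and no beat tracking
  handles within-sequence tempo changes.
* The Fourier beat is undefined below the window's low edge and above
  Nyquist; sequences with IOIs longer than ~10 s need the window and/or
  sampling rate adjusted.
* Sturges binning is sensitive to pooled-range outliers (a single long
  IOI stretches every bin); the histogram reports what it binned, and
  the mode-refinement step deliberately works on raw IOIs to reduce that
  sensitivity.
* The isochrony classification caveats above (trivial fits at large
  multiples; conservative signal label under jitter).
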