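# Methods

This note documents the models, conventions and numerical choices behind
`actispot`, and what the synthetic study conditions do and do not show.

## Signal model and conventions

A recording is one or more device streams (timestamp in integer
milliseconds since recording start, 3-axis acceleration in m/s²) plus
half-open labeled intervals `[start_ms, end_ms)`.  Milliseconds suffice at
the 40–50 Hz rates of wrist-worn devices; half-open intervals make
abutting spans non-overlapping everywhere (labels, slices, candidates).
Irregular sampling is tolerated on read (Android pushes sensor values, so
jitter is expected); operations that need a fixed rate resample first by
linear interpolation onto the grid `k · 1000 / rate` ms.  Cross-device
alignment is supported only as a constant offset shift — locating the
alignment moment (e.g. the first walking peaks after an idle period) is
external to the package.

## Preprocessing

* **Gravity/linear decomposition.**  First-order exponential IIR,
  `g[t] = α·g[t−1] + (1−α)·a[t]`, `g[0] = a[0]`, `linear = raw − gravity`.
  α defaults to 0.8, the conventional smartphone gravity-filter setting;
  the filter order/cutoff is otherwise unconstrained by the problem, so
  the single parameter is exposed rather than hidden.  Gravity + linear
  reconstructs the raw signal exactly by construction.
* **Magnitude reduction** discards orientation — useful for matching one
  kind of motion across wrist poses, harmful when distinct motions must
  stay distinguishable (see the scenario defaults below).
* **Axis angles** are `arccos` of the normalized components, i.e. the
  angle between the instantaneous acceleration vector and each positive
  axis; all-zero samples map to zero angles with a logged warning.
* **Windowed features** (complex activities): per window and channel, the
  *energy* — mean power of the mean-removed window, computed via the FFT
  (for a pure sinusoid of amplitude A over whole periods this equals
  A²/2, the variance) — and the *median absolute deviation*.  The mean
  removal keeps constant offsets (gravity, posture) out of the energy.
  Window default: 800 ms (32 samples at 40 Hz) with 50 % hop; the windows
  need only be short relative to an activity, and 0.8 s resolves the
  burst/sustain structure of arm movements at these rates.

## DTW core

The recursion `d(i,j) = cost(i,j) + min(d(i,j−1), d(i−1,j), d(i−1,j−1))`
with Euclidean cost; steps {(1,0),(0,1),(1,1)}, no step weights, no global
band (a band is available as a speed knob but off by default).
Backtracking tie-breaks are fixed — diagonal, then vertical, then
horizontal — for bit-reproducibility.  The subsequence variant initializes
the first template row with the local cost at every series position (free
start), so the last accumulated row holds the cheapest whole-template
match ending at each position; candidate spans are strict local minima of
that row (plateaus resolve to their leftmost index, boundary positions
count), with starts recovered by backtracking.

Distances are normalized by warping-path length by default so that
templates of different lengths produce comparable scores (raw distances
are retained in every result object).  The accumulation kernels are
numba-compiled; the recurrence's serial dependency rules out vectorized
numpy.

Correctness is anchored to brute force: full DTW must agree exactly with
the minimum over all explicitly enumerated monotone warping paths, and the
subsequence row with the minimum of full DTW over every (start, end)
window, on hundreds of random 1-D and 3-D instances.

## Matching and selection

Candidates from all activity templates are pooled, then the selection rule
runs once on the pooled list:

* **δ-exclusion**: greedy by ascending distance; accept iff the start is
  ≥ δ from every accepted start; stop at k.  δ defaults to 2000 ms —
  distinct activities are assumed not to begin closer together than that.
  δ is measured between *start* times; the accepted set for k is a prefix
  of the accepted set for k+1, which makes recall monotone in k.
* **zeroline**: a template cut from a period of no movement is matched by
  subsequence DTW like any other; an activity candidate survives only if
  its distance is strictly smaller than the zeroline distance at the same
  end position.  Both profiles must be on the same scale, so the zeroline
  last row is normalized positionwise by the warping-path length obtained
  by backtracking from every end position.  The zeroline template is
  truncated to the median activity-template duration so both accumulate
  over comparable path lengths.  An empty result is meaningful: idle
  explains the whole recording better than the activity template does.
* **Sliding fixed-length matcher** (single-activity scenario): full DTW of
  the template against every window of template length (default stride 5
  samples; stride 1 for exact tests).  The recommended span inherits the
  template's duration — the known boundary-accuracy limitation of this
  matcher.
* **Best-subset selection**: with several per-template best matches, score
  every size-k subset by mean pairwise Jaccard overlap and keep the
  argmax (exhaustive by design, refusing above 10⁶ subsets; ties resolve
  to the lexicographically smallest index set).  Templates that found the
  real activity agree with each other; mislocalized ones scatter.

Templates record a fingerprint of the preprocessing configuration they
were built under; matching refuses templates whose fingerprint does not
match the active configuration.

### Scenario defaults

* *Picking* (single grab, one wristband): 3-axis linear acceleration,
  sliding fixed-length matcher, best-subset k = 6.  Magnitude reduction is
  avoided here because distinct bursts become indistinguishable once
  orientation is discarded.
* *ADL* (multiple similar activities): linear acceleration reduced to
  magnitude, subsequence matcher, δ-exclusion with k ∈ [5, 20].  Templates
  are truncated to the leading 2000 ms of each label — the initial
  reaching motion shared by eat/drink/medicine activities; the activity
  label itself extends far beyond the matched part, and distinguishing
  *which* consumption activity it was is deliberately left to the
  annotator.
* *Complex/kitchen*: windowed features over the full 3-axis linear
  signal, clustering instead of direct matching.

## Clustering

Pairwise normalized DTW distances over the templates' feature sequences
feed scipy's agglomerative linkage (average by default — least sensitive
to the chaining/compactness trade-off; complete and single are options).
Feature dimensions are z-scored globally across all windows of all
templates before DTW: energy scales with squared amplitude, and without
standardization the most vigorous templates' internal spread swamps the
between-class structure.  Dendrograms export as Newick (leaf branch
length = parent merge height; internal branch = height difference) and as
a JSON merge list; cuts renumber clusters by their smallest leaf index so
partitions are order-invariant.

The un-normalized distance mode reproduces the known length bias of
accumulated DTW costs (short templates look closer); path-length
normalization, the default, removes most of it.

## Evaluation

Overlap is intersection-over-union of spans (symmetric, bounded;
intersection-over-truth is available as an alternative).  Distance
aggregation runs per candidate → nearest label: 0 on overlap, else the
gap in seconds; a configuration is summarized by min/median/max over all
candidates (leave-one-recording-out pools candidates across folds).
Recall counts a label as found if any candidate overlaps it.  ROC curves
discretize the timeline into 1 s windows: a window is positive iff it
overlaps a label, its score is minus the best candidate distance touching
it (windows without candidates rank last); the threshold sweep uses the
standard construction.  The (template count × k) sweep samples templates
with a fixed, logged seed.

## Synthetic study conditions

The generator emulates the recording protocol the matcher targets: the
wearer idles ≥ 5 s, performs up to four activities separated by ≥ 3 s
(so δ = 2 s can isolate them), and idles again.  Signal = constant gravity
vector + white Gaussian noise + planted motifs.  An activity is a *reach
burst* (sum of 2–3 Gaussian-windowed sinusoids with class-specific
frequencies and axis mixes, 1.2–3.5 s, peak amplitude 2–4 m/s²,
time-scaled by a 0.8–1.25 execution-speed factor) followed, for
consumption-style classes, by a *sustained phase* of lower-amplitude
quasi-periodic motion (hand-to-mouth pace 0.8–1.6 Hz); the ground-truth
label covers burst + sustain, mirroring how full activities are annotated
while only their onset is matched.  Defaults: 40 Hz, 120 s recordings
(the emulated protocol spans 1–3 minutes), noise σ = 0.15 m/s² (a quiet
wrist at rest), which puts the in-activity/idle mean linear-magnitude
ratio above 3.  Bilateral mode adds a left-wrist stream performing the
same activities with extra amplitude/speed jitter (a less consistent
non-dominant hand).

What passing on these conditions shows: the pipeline recovers warped,
amplitude-varied instances of known motion classes against a stationary
noise floor, end to end and deterministically from a seed.  What it does
not show: robustness to posture changes mid-recording, sensor drift or
saturation, correlated physiological noise, activities that blend into
one another, or annotation disagreement about true boundaries — none of
which the generator models.

Problem sizes used by the test suite and acceptance script (chosen to
exercise every stage at desk scale): DTW oracles on 500 (full) and 200
(subsequence) random instances of length ≤ 7; ADL cohorts of 10 × 120 s
recordings with 4 activities, matched with 2 templates at k = 10 under
leave-one-recording-out; clustering fixtures of 3 classes × 5 templates
(the kitchen class set, whose classes have tight characteristic
intensities) at noise σ = 0.15 and σ = 0.35 (magnitude ratio ≈ 2);
a picking cohort of 6 faithful + 2 off-class templates for the
best-subset comparison.

## Degenerate inputs and tie-breaks

Empty sequences, dimension mismatches, inverted intervals, all-zero
acceleration samples, streams shorter than a template or a feature
window, and single-class ROC inputs all raise typed errors or are handled
as documented rather than propagating NaNs.  All tie-breaks (backtracking
step order, plateau minima, candidate ordering, subset ties, cluster
renumbering) are fixed and deterministic; two runs of any pipeline on the
same inputs produce byte-identical outputs.

## Known limitations

The sliding matcher fixes the recommended duration to the template's.
Subsequence matching with k greater than the number of true activities
necessarily recommends spurious spans; the zeroline rule can instead
return nothing when idle dominates.  Exhaustive best-subset selection is
deliberately bounded.  Clustering quality depends on the window length
matching the motion's time scale, and feature standardization assumes the
template set is representative.  None of the components model gyroscope
or magnetometer data.
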