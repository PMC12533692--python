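# Methods

## Neural states and the segmentation model

The recording of one region during one 30-s block is a matrix `X` of shape
(T = 1920 timepoints at 64 Hz) × (electrodes). The model behind the analysis
is piecewise stability: the multivariate pattern `x_t` is drawn around a state
-specific mean pattern that holds for a contiguous stretch and then changes
abruptly. A segmentation is the ordered set of boundary indices `0 < b₁ < … <
b_{k−1} < T` (a boundary is the first sample of a new state).

**Greedy search.** The fit of a segmentation is

    fit = (1/T) Σ_t corr(x_t, x̄_{s(t)})

the mean Pearson correlation (across electrodes) between each timepoint's
pattern and the mean pattern of its state; a single-timepoint state
contributes 1 by construction. Starting from one state, each iteration places
the candidate boundary maximizing the fit. The *states* variant can place a
full state (two boundaries) per iteration, which rescues short states embedded
in longer ones (pattern A–B–A): a lone boundary inside such a stretch gains
little, but the pair delimiting B gains a lot. The default two-stage search
places the best single boundary and then the best *completing* boundary inside
the state just split; the completion is accepted only when its gain beats the
best single-boundary gain available in any other state — i.e. when it merely
anticipates the next greedy step. Without that guard, any extra boundary
raises the raw fit and the pair step would flood the path with noise-level
boundaries. An exhaustive pair mode (quadratic per state) is the oracle for
small inputs; it accepts a pair only when its joint gain beats two sequential
single placements. Fit ties resolve to the earliest candidate index, so the
algorithm is fully deterministic. With fine-tuning on (default), each existing
boundary may shift by one sample after every iteration (one sweep) when that
improves the fit.

The greedy path stores a segmentation at every k up to `k_max` (library
default `floor(T/2)`; the analyses here cap it at 25–60 since the selected k
under the study conditions is an order of magnitude below `T/2` — the cap is
exposed as a parameter). Intermediate single-boundary snapshots inside a
pair iteration are recorded before the end-of-iteration fine-tune sweep.

**Model selection: t-distance.** For a candidate segmentation, pool (a) the
Pearson correlations of all timepoint pairs lying within one state and (b)
all pairs spanning two *consecutive* states (non-adjacent pairs are excluded,
so very distant comparisons cannot dominate). The t-distance is the pooled
-variance two-sample Student t between pools (a) and (b), computed on raw
correlations without Fisher transform. It is undefined (reported missing)
when either pool is empty; when both pools have zero variance it is 0 for
equal means and ±∞ otherwise (the perfectly block-diagonal case). Summed-area
tables over the T × T correlation matrix make each evaluation O(k) after an
O(T²) setup.

**Cross-block stabilization.** Per-block argmax selection of k is noisy on
single-subject electrophysiology. The per-block t-distance curves are
averaged on the union k grid and the global `k*` is the argmax of the mean
curve (ties → smallest k). Each block then adopts the peak of its own curve
closest to `k*`, where a peak is a point — or a pair of adjacent points with
the exact same value — strictly above both neighbors; plateau pairs are
represented by their lower k, equidistant peaks resolve to the smaller k, and
a peakless (monotone) curve falls back to its argmax with a warning.

## The Gaussian match and its null

Boundary timelines are binary marks on the 64-Hz grid, kept per 30-s speech
block. Stimulus timelines place a mark at the nearest grid sample (half-up
rounding) of every event onset and offset, merging an offset that coincides
with the next onset into a single mark; neural timelines mark segmentation
boundaries (block starts are not marks).

For a seed timeline `S` and another timeline `O`,

    match(S → O) = mean over marks s∈S of exp(−Δ(s)² / (2σ²)),  σ = 332 ms

where `Δ(s)` is the distance from `s` to the closest mark of `O` *within the
same block* (blocks are separate stretches of the stimulus; the search never
crosses a block edge). The statistic is deliberately asymmetric: comparing
stimulus features to neural boundaries, the stimulus timeline seeds, so extra
neural boundaries cannot depress the match; comparing two regions, the
timeline with fewer marks seeds (ties keep the first argument). Marks are
pooled across blocks by default (`pooling="per_block"` averages block means
instead). Seed marks in a block where `O` has no marks are excluded from the
mean — a "closest mark in any block" rule would let one empty block inject
arbitrary near-zero weights. σ is a fixed design constant: large enough that
genuinely co-occurring boundaries a few samples apart still count, small
enough that the chance-level match stays informative; no σ sweep is performed.

**Delays.** The match is computed over a grid of integer-sample delays
applied to the seed: 0…38 samples (0–593.75 ms; 600 ms is not a grid
multiple, the grid stops at the last step inside the range) against a
stimulus, −38…38 between regions. Marks shifted past a block edge are
dropped, not wrapped. The optimal delay is the argmax; ties resolve to the
smallest |delay|, then the smallest delay. Between regions the reported
delay is re-signed to a fixed convention — high-level relative to low-level —
so a negative optimal delay always means high-level boundaries lead
(top-down).

**Relative match.** `match_data` is the max over the delay grid. For the
null, the state durations of one timeline (the neural one against a stimulus
seed; the non-seed region otherwise; selectable) are randomly permuted per
block — preserving the mark count and the duration multiset, destroying
alignment — and the max-over-delays match recomputed; `match_null` is the
mean over 1,000 permutations and

    relative = (match_data − match_null) / (1 − match_null).

All permutations derive from one explicit generator and are reproducible.

## Group statistics

Per-subject relative matches are tested against zero with the Wilcoxon
signed-rank test (zeros dropped; exact distribution for n ≤ 25 including tied
ranks, normal approximation beyond; one-tailed for alignment, two-tailed for
the delay contrast). The delay contrast takes `delay_high − delay_low` per
subject for the clause alignment, restricted to subjects whose relative match
exceeds 0 in both regions (a delay is meaningless where alignment is at
chance; the criterion is switchable to a permutation quantile). No multiple
-testing correction is applied across the feature × region analyses; p-values
are reported raw. The matched-state-count control re-runs the alignment with
every block forced to the greedy-path solution of a given per-block boundary
count (nearest achievable count if absent, logged) to separate granularity
effects from genuine boundary placement. Median state duration per region is
the median of pooled block durations, reported without a group test.

## Preprocessing

Fixed order: drop bad-flagged channels → 0.1 Hz high-pass → despike →
common-average reference → 50 Hz notch (2 Hz width) → ROI channel selection →
polyphase downsample to 64 Hz → clip at μ ± 3σ (pre-clip moments) → z-score
(post-clip moments, so the output mean is exactly 0). All filters are
zero-phase (forward–backward), because the delay analyses cannot tolerate
filter-induced lag; the high-pass uses padding of three filter time constants
since its ~10-s settling would otherwise leak into block edges. Despiking
flags samples whose robust z (median/MAD) exceeds 8 and linearly interpolates
across flagged runs; more than 50% flagged in a channel is an error.
ICA-based re-referencing requires visual component selection and is out of
scope; `reference="none"` accepts externally re-referenced data. Z-scoring is
per speech block by default (matching the per-block segmentation),
configurable to run-wide. Regions are defined per electrode from Brodmann
areas: low-level language 20/21/22/41/42, high-level 38/39/40/44/45/46/47.

## Synthetic cohorts

The generator emulates exactly the structure the analyses assume, at the
study's scale: 6 speech blocks × 30 s × 64 Hz per subject, two regions of 12
channels. Low-level boundaries are drawn per block (15–40 states, uniform
composition with an 8-sample minimum duration); the high-level region copies
70% of them shifted by the planted lag (−123 ms: high-level leads) and draws
the rest independently. Each state emits a unit-norm mean pattern
(independent Gaussian by default; mutually orthonormal in the recovery
benchmark, where cleanly separated states are the point) plus white Gaussian
noise of SD 0.3 per channel (AR(1) noise optional, default off). States
switch instantaneously — the piecewise-stable definition of a neural state.
A clause-like event table designates half of the shared boundaries as
on-/offset marks placed 150 ms before the low-level boundary with 1 sample of
jitter, 5% spurious marks and 5% dropped; the implied high-level stimulus
delay is 150 − 123 = 27 ms. Null cohorts set the shared fraction to 0 and
unlock events from boundaries entirely. Recordings are emitted post
-preprocessing (64 Hz, z-scored); a raw mode emits 512 Hz with 50-Hz line
noise, slow drift, impulsive spikes and one bad channel to exercise the
cleaning chain.

What the generator does *not* emulate: realistic ECoG spectra (real signal is
broadband, not a step process — which is also why the preprocessing
-transparency check uses band-limited noise: a 0.1-Hz high-pass genuinely
removes part of a pure step-process's power), volume conduction, electrode
-placement variability, and non-stationary noise. Passing tests therefore
demonstrate the correctness and calibration of the machinery under the stated
model, not performance on any particular patient dataset.

## Numerical choices and problem sizes

- Greedy fit evaluation is O(T·C) per iteration via prefix sums of the raw
  and row-standardized data; a zero-variance segment mean contributes 0.
- The recovery benchmark uses 20 blocks of 10 orthogonal-pattern states with
  a 96-sample minimum duration (half the mean duration), noise SD 0.3, and a
  greedy cap of k_max = 25; measured: t-distance argmax within ±1 of 10 in
  ≥ 18/20 blocks, ≥ 90% of boundaries within ±1 sample.
- Null calibration runs 100 replicate cohorts of 10 subjects at 200
  permutations per subject — the permutation count is reduced from the
  production 1,000 since the null mean converges well before that, and the
  rejection-rate check needs replicates more than permutations.
- Delay recovery uses ground-truth boundary timelines (the match layer's own
  statistical surface); end-to-end GSBS→match delay recovery is exercised
  separately in the stats tests.
- Exact Wilcoxon p-values are validated against full 2ⁿ sign enumeration.

## Known limitations

- The two-stage pair search is not guaranteed to find the globally best
  boundary pair (the exhaustive mode is, and both agree on the constructed
  embedded-state cases); adversarial patterns could differ.
- The pooled t-distance rewards large pools: states much shorter than their
  neighbors can be absorbed with a net t gain, so very short genuine states
  may be under-segmented near the optimum — visible in the generator's
  default (non-orthogonal, short-state) regime, where the selected k sits
  below the planted count while boundary locations remain accurate.
- Real annotation timelines (word/clause tallies of a specific stimulus) are
  consumed as input tables; this repository validates the counting rules on
  synthetic tables only.
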