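# Methods

`sensorlight` implements a sensor-space spatiotemporal searchlight
decoding analysis for epoched MEG-like recordings, together with a
synthetic-data generator that makes the whole chain verifiable by
parameter recovery. This note documents the models, the tunable
parameters and their defaults, the numerical choices, and what the
synthetic validation does and does not show about real data.

## Synthetic data

**Sensor layout.** A regular planar grid stands in for a whole-head
gradiometer array (flattened 2-D view). The neighbor relation is
`0 < distance < threshold`; the default threshold of `1.2 × spacing`
admits axial neighbors only, giving interior channels a 4-neighborhood,
edge channels 3 and corners 2. The same graph is used by the planar
transform, the searchlight channel sets and the cluster adjacency, as a
single structure should be.

**Stimulus table.** Items carry an object category (animal / food / tool
/ clothes, balanced ±1), a syllable count (mostly 1–2, a few 3),
a phonological neighborhood density count, a per-million word frequency,
and three image-level visual features (contrast, edge density,
colorfulness) sampled independently of the lexical variables. The three
lexical covariates are coupled through a Gaussian copula whose latent
correlation matrix is calibrated on a large fixed-seed sample so that the
*realized* Pearson correlations of the discrete/skewed marginals hit the
targets — by default length–density −0.67, frequency–length −0.37,
frequency–density +0.32, the entanglement structure typical of
picture-naming item sets. Discretization attenuates latent correlations,
so the calibration inflates them (a fixed-point iteration, shrunk back to
the elliptope when a target is not exactly attainable); a target matrix
that is not positive semidefinite is rejected. Marginals: syllable
counts with probabilities (0.485, 0.493, 0.022); neighbor counts as a
rounded lognormal (median 9, log-SD 0.65, range ≈ 1–50); frequency as a
lognormal (median 4.8 per million, log-SD 0.9). Derived labels:
`length_class` (short = monosyllabic), `density_class` (rank quartiles,
ties to the lower class), and low/high median splits of each visual
feature.

**Epochs.** One `EpochSet` per subject: per-channel white Gaussian noise
(optional 1/f shaping) plus, for each injected effect, a per-class
amplitude × a flat-top envelope with 10 ms half-cosine ramps on the
effect's channels inside its window. Optional per-channel weights let an
effect alternate in sign across its region (a checkerboard), mimicking
the spatially differentiated field pattern that a planar transform
responds to — a spatially uniform offset has zero tangential gradient in
the interior of its region and would largely vanish under the transform.
A configurable fraction of trials is flagged invalid (default 0.17,
emulating the ~3 % naming errors plus ~14 % disfluencies typically
excluded), and a configurable fraction receives one contiguous
single-channel artifact segment in the missing mask (default: 5 % of
trials, 100 ms). Injected effects are recorded in
`EpochSet.info["effects"]` as ground truth.

## Preprocessing

**Bandpass + decimation.** Zero-phase 4th-order Butterworth bandpass
(default 1–30 Hz) via forward–backward filtering, then integer-factor
decimation. The target rate must divide the input rate; masked samples
are linearly interpolated before filtering so the IIR filter never sees
NaN, and the mask is propagated conservatively (a decimated cell is
missing if any source cell in its block was). Note that zero-phase
filtering is non-causal: a transient leaks backward by roughly one
filter ringing period (~30 ms at the 30 Hz edge), which slightly
advances apparent onsets — visible in the recovery results below.

**Planar gradients.** For each channel, the horizontal and vertical
tangential derivatives are the least-squares plane fit to the field
differences toward its first-order neighbors (`g = pinv(Δpositions) ·
ΔF`). On a regular grid this reproduces a linear field's slope exactly
and is linear in the field. Channels without neighbors are flagged and
set missing; a planar cell is missing if the channel or any neighbor
feeding it is missing. Components are combined per sample as the
Euclidean norm √(h² + v²) — non-negative, rotation-invariant, and maximal
above the source, which is what makes sensor-level topographies
interpretable.

## Searchlight decoding

A searchlight at (channel, time) collects the channel's first-order
neighbors (plus the center by default) and a 150 ms window — 45 samples
at 300 Hz; feature vectors are flattened channel-major. Window alignment
is **trailing** by default: the window ends at the evaluation time, so
the decoder at time *t* sees only data up to *t* and an effect can never
be detected before its onset (up to filter leakage). A centered window
is the symmetric alternative and is available, but it reads up to half a
window of post-onset signal into pre-onset time points and biases onset
estimates early, which defeats latency-ordering questions. Centers whose
window does not fit in the epoch are marked undefined, never truncated.

The classifier is Gaussian naive Bayes: class priors from training
frequencies, per-feature maximum-likelihood means and variances, variance
floored at `1e-9 ×` the mean feature variance (guarding degenerate
features; shared per fold across all searchlight centers so that every
cell of a map is fitted under the same policy). Prediction is the argmax
of log prior + summed log densities, ties to the lexicographically first
class.

Cross-validation: random undersampling equalizes class counts once per
repeat *before* fold assignment (so training and test sets are both
balanced), stratified 5-fold splits, 5 repeats with fresh folds, and the
pooled fraction of correct test predictions is reported (equal to the
mean of fold accuracies up to ±1-trial fold-size effects).
Undersampling and fold assignment are derived from (seed, repeat) and
shared across searchlight centers — this is what "undersample once per
repeat" means operationally, and it is also what makes the map engine
factorizable. Trials with any masked cell inside a given searchlight are
excluded at that center on both the training and the test side.

**Fast engine.** Because the naive Bayes log-likelihood is a sum of
independent per-feature terms, per-cell CV factorizes: class statistics
and per-trial log densities are computed once per (channel, sample), then
aggregated per center by a windowed cumulative sum over time and a sparse
adjacency product over channels. Centers whose searchlight contains
masked *training* cells are recomputed with corrected statistics, grouped
by identical dropped-trial patterns. The engine is exactly equivalent to
the per-cell reference implementation (`engine="exact"`), and the test
suite asserts bitwise-equal maps on masked fixtures. A float32 mode
roughly halves runtime; the pipeline uses it, and predictions were
verified identical to float64 on the demo data.

## Inference

**Empirical null and Z scores.** Chance level is estimated per subject
and per cell by recomputing the decoding map under label randomizations
(reference count 100) and Z-standardizing the observed accuracy by the
null mean and SD. Randomization is constrained to strata: labels are
permuted within each stratum only, so any decodable structure carried by
the stratum variable is present in the null, and the Z score isolates the
target variable's own contribution. Default strata: the category null is
constrained to the joint low/high bins of the three visual features
(visual-confound control); each phonological variable's null is
constrained jointly to category × the other phonological variable,
because the two are entangled by construction (r ≈ −0.67) and a
category-only constraint leaves each one decodable through the other —
directly visible in recovery experiments as a spurious early onset for
the later variable. Singleton strata keep their label fixed (logged).

**Cluster-based permutation test.** Per cell, a one-sample *t* of the
subject Z scores against 0; cells above the one-sided critical *t* at the
cluster-forming alpha are clustered by spatial adjacency (the searchlight
neighbor graph, same time point) plus temporal adjacency (same channel,
consecutive centers; no diagonal space–time edges). Cluster mass is the
sum of *t* values; the familywise null is the maximum cluster mass under
random sign-flips of whole-subject Z maps (the standard one-sample
scheme), with exact enumeration available for small groups. P-values use
the add-one estimator and are never exactly zero. Sign-flipping leaves
per-cell squared sums unchanged, so only the per-cell mean is recomputed
per permutation.

The cluster-forming default is 0.05. The demo pipeline forms clusters at
0.01 instead: familywise validity holds at any forming threshold, but at
a lenient one the spatially correlated noise around a true effect bridges
into the significant cluster, and cluster extent and onset then localize
poorly — with the stricter threshold, recovered onsets land within one
time-step of the injected ones instead of 50–120 ms early. This is the
well-known cluster-extent caveat, not a property of this implementation.

## Demo configuration and recovery metrics

The default `PipelineConfig` simulates 12 subjects, an 8×8 grid, 60 items
× 3 repetitions, generation at 300 Hz, bandpass 1–30 Hz, decimation to
100 Hz, searchlight maps every 3rd sample (30 ms grid), 12 randomizations
per null and 800 cluster permutations — desk-scale sizes chosen so the
full pipeline runs in a few minutes; the reference analysis values
(100 randomizations, 2000 permutations, full sample rate) remain the
documented defaults of the underlying functions. Three effects are
injected in distinct regions at staggered windows (category 150–250 ms,
word length 250–350 ms, neighborhood density 350–450 ms) with
checkerboard channel weights and amplitudes placed so searchlight
accuracies land moderately above chance (≈ 0.35–0.45 for the 4-way
contrasts, ≈ 0.6–0.7 binary) rather than at ceiling — at ceiling even
the faint backward leak of the zero-phase filter becomes decodable and
smears onsets.

Recovery compares significant clusters to the injected ground truth:
onset = earliest center time over significant clusters (trailing windows
make this an essentially unbiased estimate up to the time grid and filter
leak), onset error against the injected window start, and the Jaccard
overlap between the union of significant-cluster channels and the
injected channel set. Because the planar transform spreads signal one
neighbor hop and the searchlight another, a perfectly recovered region is
expected to be a dilation of the injected one; Jaccard values around
0.4–0.65 at grid scale are what clean recovery looks like.

## What the synthetic validation does and does not show

The generator exercises every code path the analysis has: masked
samples, invalid trials, unbalanced classes, entangled covariates,
planar-transform geometry. It does not emulate realistic MEG physics —
no forward model, no spatially correlated sensor noise, no cardiac or
ocular artifact waveforms (masks stand in), and white noise by default
(a 1/f option exists). Passing recovery therefore demonstrates the
correctness and calibration of the *estimator chain*, not performance on
real recordings; raw accuracy levels on real data depend on physiology
and preprocessing quality and cannot be reproduced from simulation.

## Numerical choices

- Variance floor `1e-9 × mean feature variance` (absolute `1e-12` when
  all variances vanish); shared per fold across centers.
- Argmax ties: lexicographically first class. Quantile ties: lower
  class. Both make the pipelines pure functions of their inputs.
- Undersampling, folds, shuffles and sign-flips all draw from
  `numpy.random.Generator` seeded via `SeedSequence` from a single root
  seed; identical configs reproduce byte-identical outputs.
- Edge detection for stimulus images: Sobel magnitude over a
  luminance-weighted grayscale (0.299/0.587/0.114), threshold fixed at
  10 % of the maximum attainable magnitude, so "percentage of edge
  pixels" is well defined.
- Contrast: mean 3×3 local intensity variance; colorfulness: the
  opponent-channel statistic `σ_rgyb + 0.3 μ_rgyb` on 0–255 channels.

## Known limitations

- The planar estimate uses a local plane fit; with fewer than two
  non-collinear neighbors the gradient is the minimum-norm solution.
- Decimation requires an integer factor; arbitrary resampling is out of
  scope.
- Cluster extent should not be read as a localization statement
  (standard caveat); the demo's stricter forming threshold mitigates but
  does not remove it.
- The empirical null at desk scale (12 randomizations) inflates Z
  variance by ~10 % relative to the 100-randomization reference; the
  group-level t statistic absorbs this.
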