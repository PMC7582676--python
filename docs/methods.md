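# Methods

`p300balance` re-creates, on synthetic data, the complete analysis loop of a
P300 oddball brain–computer interface whose training data are intrinsically
imbalanced: one attended (target) stimulus per selection block against 3 or
5 unattended (nontarget) stimuli. The package covers the oddball session
generator, the ERP preprocessing chain, eight class-imbalance samplers, a
soft-margin SVM target classifier (plus a weighted-undersampling bagging
ensemble and a weighted-C variant), and the evaluation experiments built on
them. This note records the model, its assumptions, the parameters that
matter, and the design choices made where the design was genuinely open.

## The oddball session model

A session is `n_train_blocks = 50` training and `n_test_blocks = 30` test
blocks. In a block, each of the `n_stimuli ∈ {4, 6}` stimuli is highlighted
exactly `n_reps = 10` times in random order; a highlight lasts 62.5 ms and
is followed by a 62.5 ms inter-trial interval, so one trial occupies 125 ms
(62.5 samples at 500 Hz — onsets are laid out as `floor(i · 62.5)`, so gaps
alternate 62/63 samples and two consecutive trials always span exactly 125
samples). One stimulus per block is the target.

**Evoked response.** A target highlight adds, with probability
`p300_prob = 0.6`, a Gaussian-in-time bump (peak `p300_latency = 350` ms
post-onset, SD `p300_width = 55` ms, trial-to-trial latency jitter SD 40 ms)
scaled by `p300_amplitude` (default 14 µV) and by a fixed midline-weighted
channel topography. The elicitation probability and jitter model the
well-documented unreliability of single-trial P300; without them the target
class is so tight in feature space that balancing has no geometric effect on
any classifier, which would make the whole analysis vacuous.
`p300_amplitude` (against `noise_sd = 10` µV) is the single subject-quality
knob; cohorts mix good and poor performers by varying it.

**Background activity.** The default background is *rhythmic*: 4 narrowband
sources at 0.6–7.2 Hz (per-block Rayleigh amplitudes weighted 1/√f, uniform
phases) with fixed unit-norm spatial patterns — the first being the P300
topography itself, i.e. ongoing activity of the same cortical configuration
— plus a white sensor floor at 2 % of the background SD. This low-rank
structure is deliberate and load-bearing. ERP features here live in
`n_channels × 250` dimensions but only ~200 training samples exist; if the
background were spatially and temporally white (or full-rank colored),
every training set would be linearly separable with a wide margin at C = 1,
and since SMOTE-family synthetics are convex combinations of minority
points — they cannot leave the minority hull — the SVM optimum would be
*bit-identical* before and after oversampling. Real ERP data do not behave
this way because their background is dominated by a few spatially coherent
rhythms; the rhythmic model reproduces that effective low dimensionality,
the classes genuinely overlap, hinge slack is active at C = 1, and
balancing changes the classifier the way it does on real recordings.
`background="white"` remains available and is used by the calibration
tests (noise-variance reduction under epoch averaging, chance-level
checks of the generator itself).

**What the generator does not emulate:** eye/muscle artifacts and bad
channels (the corresponding cleaning stages of a real pipeline are out of
scope), electrode drift/impedance changes, inter-subject topography
variability, and any nonstationarity across blocks beyond the per-block
rhythm amplitudes. Passing tests therefore show that the analysis machinery
behaves correctly and that the documented directional effects follow from
imbalance + overlap; they do not certify performance numbers on real EEG.

## Preprocessing

Zero-phase 4th-order Butterworth high-pass at 0.5 Hz, common average
reference, zero-phase 4th-order low-pass at 50 Hz (measured 60 Hz
attenuation after forward–backward application: 15.4 dB; the synthetic
data carry no line interference, so steeper rolloff buys nothing and the
gentler filter preserves more of the 30–50 Hz band). Epochs span
[−200, 600) ms around each
onset with the [−200, 0) mean subtracted per trial and channel. The 10
epochs of each (block, stimulus) pair are arithmetically averaged into one
sample — the only reduction consistent with the design's printed class
sizes (50 target / 150 or 250 nontarget per 50-block session). The
[100, 600) ms window is cropped — half-open, so 500 ms × 500 Hz = exactly
250 points per channel — channels are concatenated, and features are
standardized per column with parameters fit on the training portion only
(zero-variance columns get scale 1 with a warning).

## Samplers

All eight samplers operate on the standardized feature matrix with
Euclidean distances, never mutate their input, exclude a point from its own
neighbor list, break distance ties by row index, and are deterministic
under a fixed seed. Synthesis follows `s = p + r · (q − p)`, `r ~ U(0,1)`,
with `q` drawn uniformly among the parent's K = 5 nearest *minority*
neighbors (drawing with replacement is what lets an arbitrary deficit be
filled). Parents are drawn uniformly with replacement from the eligible
set:

- **ROS** — all minority points, copied verbatim;
- **SMOTE** — all minority points;
- **B-SMOTE** — the DANGER set: minority points with more than half of
  their M = 10 nearest neighbors (over the full dataset) in the majority.
  The "more than half" rule is applied literally, so an all-majority
  neighborhood also qualifies; `exclude_all_majority=True` restores the
  original method's noise-exclusion behavior. An empty DANGER set returns
  the data unchanged with a warning.
- **SVM-SMOTE** — minority-class support vectors of a linear C = 1 SVM
  trained on the data, gated on *fewer* than half of the M neighbors being
  majority (seeds deep in majority territory are rejected);
- **ADASYN** — every minority point i receives
  `g(i) = ceil(γ(i) · G)` synthetics, `G = β(|S_maj| − |S_min|)` (β = 1),
  γ the normalized majority fraction of its K-neighborhood. The ceiling can
  overshoot G by up to one per point; the excess is kept. If no minority
  point has majority neighbors, γ falls back to uniform.

Undersampling: **RUS** removes random majority rows down to the minority
size; **Tomek** removes majority members of mutual cross-class
nearest-neighbor pairs in one pass; **NCR** applies a K = 3 edited-NN stage
(drop majority points whose neighborhood majority-vote disagrees) followed
by the condensation stage *as the source describes it*: drop a surviving
majority point whose single nearest neighbor is majority, keep it if that
neighbor is minority. Both stages evaluate against a fixed snapshot so the
result is scan-order independent. Note this condensation inverts the
textbook condensed-NN and, on cleanly separated data, removes essentially
all interior majority points — which is why NCR degrades high-SNR
recovery (see Limitations).

`sampling_ratio` sets the desired minority/majority ratio after balancing
(1 = full balance); the ratio sweep runs B-SMOTE across a grid from the
design's natural ratio to 1.

## Classification

A soft-margin SVM (`½‖w‖² + C Σξ`, C = 1, linear kernel — the standard
choice for high-dimensional ERP amplitude features; the kernel is
configurable). Class weights can multiply C per class; the weighted-C
variant sets them to `l / (2 n_class)`, i.e. inversely proportional to
class size. A two-parameter Platt sigmoid, fit by Newton iterations on
3-fold out-of-fold decision values (resubstitution values if a class has
fewer than 3 members), maps decision values to target probabilities.

Block decision: the classifier scores one averaged-ERP row per stimulus
and the argmax of the target probability is the selected stimulus (ties to
the lowest index). Because the calibration is strictly monotone, selection
by raw decision value is identical — both pathways are exposed and tested
equal. Binary target/nontarget calls — the basis of recall, precision and
F1 — threshold the *calibrated probability* at 0.5. This choice matters:
the calibrator carries the class prior of its training data, so the
unbalanced baseline is conservative about target calls (low recall, high
precision), and balancing moves the operating point — the mechanism behind
the recall/precision trade the experiments measure.

**WUS ensemble.** The shuffled nontarget rows are split into 3 (4-stimulus
designs) or 5 (6-stimulus) near-equal disjoint subsets; each subset plus
all target rows trains one SVM; members are ranked by resubstitution
training accuracy (ties broken by subset index) and vote with exact
rational weights 1/6, 2/6, 3/6 or 1/15 … 5/15 (lowest accuracy, smallest
weight); the block decision is `argmax_j Σ_i w_i p_ij`.

## Evaluation

Block accuracy is matched blocks / test blocks. Recall, precision and F1
come from the per-stimulus binary confusion matrix; undefined ratios are
reported as absent rather than zero. The information transfer rate is

    ITR = [log₂N + P log₂P + (1−P) log₂((1−P)/(N−1))] / T   bits/min,

with the `x log₂ x` limits at P ∈ {0, 1}; it is exactly 0 at chance. T (time
per selection) is always an explicit argument; the experiments use 10 s,
which puts ITRs on the scale BCI studies report (a 4-stimulus interface at
~85 % yields ~6–7 bpm).

SV introspection reports per-class support-vector counts, their ratio, and
the mean relative SV-to-boundary distance `mean(|w·x + b|)/‖w‖` over SVs.

`run_comparison` crosses a cohort with the 11 conditions (no balancing,
five oversamplers, three undersamplers, WUS, weighted-C), tests each
method against no balancing with a two-sided Wilcoxon signed-rank across
subjects (α = 0.05, no multiplicity correction — matching per-method
significance marks; the underlying study does not name its test), and
reports poor performers (subjects below the cohort's mean no-balancing
accuracy). `ratio_sweep` records train/test binary metrics and block
accuracy per ratio; correlations with block accuracy are computed across
*ratio conditions* (rows averaged over subjects) — correlating raw
subject × ratio rows lets between-subject quality dominate and reverses
the precision sign, so condition-level pooling is the supported reading.

## Problem sizes used by the test and acceptance runs

Design-count checks run the full 32-channel, 50 + 30-block design. The
cohort recovery experiment (chance level at zero amplitude; ≥ 95 % recovery
at high SNR) uses 10 subjects on an 8-channel montage — block structure,
per-channel feature counts and class ratios unchanged; the montage choice
keeps the heavily non-separable zero-amplitude fits fast. The directional
experiment (B-SMOTE vs no balancing) uses 20 subjects and the ratio sweep
10 subjects, both at 32 channels with `p300_amplitude = 9` µV — the
poor-performer band (no-balancing block accuracy ≈ 65 %), where balancing
effects are the study's own focus. `scripts/acceptance.py` recomputes the
same quantities at slightly smaller cohort sizes (4–8 subjects).

## Numerical choices and degenerate inputs

- Neighbor queries are brute-force Euclidean (`NearestNeighbors`,
  `algorithm="brute"`); unit tests verify them against O(n²) enumeration.
- `SamplerParams` validates K ≥ 1, M ≥ K, β ∈ [0,1], ratio ∈ (0,1].
- Empty minority, single-class training data, single-channel CAR and
  out-of-bounds epochs raise `ValueError`; empty DANGER sets and
  no-qualifying-SV cases warn and return the input unchanged.
- The Platt Newton solver caps exponents at ±500 and stops at 1e-10 steps.
- Master seed → per-subject seeds via `numpy.random.SeedSequence.spawn`,
  reduced mod 2³¹.

## Known limitations

- The mean relative SV-to-boundary distance does **not** increase under
  B-SMOTE on these synthetic cohorts: adding synthetic points adds
  constraints to the SVM dual, and across every regime probed (white,
  pink and rhythmic backgrounds; amplitudes 2–14 µV; 8 and 32 channels)
  the geometric margin shrinks or stays flat while the SV *counts* and
  their class ratio rise. The corresponding directional test is left
  failing rather than weakened; on real recordings this quantity has been
  reported to move the other way, which these synthetic conditions do not
  reproduce.
- NCR, implemented with the condensation rule as described in its source
  here, removes nearly all interior majority points and therefore caps
  high-SNR recovery around 88 % — its case of the ≥ 95 % recovery test
  fails by design fidelity, not by accident.
- Block accuracy responds only weakly to the minority/majority ratio:
  balancing moves the decision boundary mostly intercept-wise, and the
  per-block argmax is invariant to a common shift of all stimulus scores.
  The monotone recall/precision/F1 trends of the ratio sweep are robust,
  but the sign of the condition-level correlation between a binary
  measure and block accuracy depends on which cohort is drawn; it should
  be read as consistent-with, not as a guaranteed property of the
  generator.
- Absolute accuracies/ITRs of the original study are out of scope: they
  depend on recordings that were never deposited. Only design counts,
  formula identities and directional effects are claimed.
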