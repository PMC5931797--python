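# Methods

`accdecode` reimplements, as a tested library, an ensemble-decoding analysis
of rat anterior cingulate cortex (ACC) activity on a figure-8 effort–reward
task: decoding the animal's position from population spiking, detecting
"excursion" events in which the decoded position shifts to the remote target
feeder, and characterizing the reward/choice information carried by the
cells active during excursions.  Because the original recordings are not
bundled with the package, a synthetic-session generator with full ground
truth stands in for them; every claim the test suite makes is a property of
the method demonstrated on that generator.

## The task and the synthetic sessions

The track is a figure-8 of 102 cm × 114 cm with three feeders: C on the
central arm and the target feeders L/R at the north corners.  A session is
organized in blocks of 16 trials — 10 forced-alternation trials followed by
6 free-choice trials — with a fixed 6-block sequence of reward volume
(30/120 µL) and barrier level (0/1/2) assignments; the sequence restarts
if the session continues (`ScheduleConfig.n_repeats`).  Free choices are drawn from a softmax over
effort-discounted reward utility, `p(R) = σ((u_R − u_L)/τ)` with
`u = w_r·(reward/120) − w_e·(level/2)`; defaults `w_r = 1`, `w_e = 0.6`,
`τ = 0.25` give block-level preferences between roughly 0.05 and 0.95.
The nominal platform heights (0/23/46 cm; the intermediate value is a
convention, with the top of the range quoted as 46 or 48 cm in different
descriptions of the task) enter the model only through the barrier level in
the utility — they never alter the trajectory geometry.  The trajectory
runs the skeleton at constant speed (default 60 cm/s, 30 Hz tracker) with
zero-speed dwells at C and the chosen target feeder.

Spikes are inhomogeneous-Poisson.  Each unit has a Gaussian tuning curve in
*geodesic* (along-track) distance from a field-centre vertex — field SD
25–45 cm, so fields span well over 50 cm — on a baseline of 0.8–1.5 Hz with
peaks of 4–12 Hz.  Geodesic distance (shortest path along the skeleton
graph) rather than a scalar linearized coordinate keeps broad tuning
well-defined on a track with two loops sharing the central arm.  Subsets of
units (default 30% each) carry multiplicative reward and/or choice gains
applied throughout the trial.

Excursions are injected during target-feeder dwells: within 1.5 s after the
feeder off-set (onset delay U(0.1, 0.5) s), for a duration drawn from
N(400, 80) ms clipped to 300–500 ms, every unit's rate is replaced by
`(1 − w)·rate(occupied feeder) + w·rate(remote feeder)` and the spikes in
the window are regenerated (default blend weight `w = 1`; spikes outside
the window are untouched, exactly).  The feeder rates are the units'
spatial-tuning rates at the feeder locations — the typical population
pattern expressed during visits there — not modulated by the current
trial's reward/choice gains: applying those gains would push the planted
pattern off the decoder's training manifold (the decoder never sees the
remote feeder's location paired with the occupied trial's gains) and the
planted "shift to the remote feeder" would not reliably decode there.  The per-trial injection probability is
`p = p0 − p1·preference(occupied side)` (defaults 0.6 / 0.5), or a fixed
trial count for recovery experiments.  The injection log is the ground
truth the detector is scored against.

What the generator does *not* emulate: theta-band or sequential
within-event structure (the injected shift is a stationary rate blend, not
a compressed trajectory), slow drift or non-stationarity of tuning,
correlated noise across units, overdispersion relative to Poisson, and
tracker artifacts.  Passing tests therefore demonstrate correctness and
sensitivity of the analysis pipeline under these idealized statistics, not
that real ACC data would yield the same effect sizes.

## Preprocessing

Trials longer than 1.5× the median trial duration are dropped, then units
with session-average rate below 0.5 Hz.  Each spike train is smoothed with
a Gaussian kernel (each spike contributes unit mass; a bin's value is the
integral of the density over the half-open bin window divided by the bin
width, i.e. a rate in Hz) and binned.  Two named profiles: **coarse**
(150 ms kernel, 50 ms bins) for position decoding and **fine** (120 ms
kernel, 20 ms bins) for excursion detection and feeder-pattern analyses.
Kernel mass is accumulated over a ±6 σ window, conserving each spike's mass
to better than 1e-6.  Binned rates are square-root transformed and
z-scored per unit, with the mean/SD estimated **on training bins only** and
reused frozen on held-out bins (which segment the statistics come from is a design choice here;
fitting on the training segment avoids leakage).  Zero-variance
units are dropped rather than imputed.  Per-bin position is the mean of the
tracker samples in the bin window (empty bins interpolated and flagged);
bins are labelled by feeder zone within a configurable radius (default
10 cm, the zone size being otherwise unspecified).

## Decoders

**Feedforward network.**  Input one unit per neuron, hidden layers of 100,
50 and 25 units (rectified-linear, rectified-linear, tanh), linear 2-D
output; mini-batch gradient descent with momentum and weight decay, batch
100, 100 epochs.  The training loss is `(1/2N) Σ ‖pred − target‖²`;
reported RMSE is `√((1/N) Σ ‖pred − target‖²)` in cm (the ½ factor lives
only in the loss).  Unstated optimizer details default to learning rate
1e-3, momentum 0.9, weight decay 1e-4, He-scaled Gaussian initialization,
all seed-controlled; forward/backward passes are plain numpy, which makes
training bit-reproducible for a given seed.  Targets are z-scaled per axis
internally (inverted at prediction time) so the fixed learning rate is
well-conditioned regardless of track size; with raw centimetre targets the
same learning rate converges far too slowly within 100 epochs.

**Bayesian reconstruction.**  Space is tiled at 4 cm × 3 cm from the
south-west origin (half-open east/north edges).  Training bins give
per-tile expected rates (floored at 1e-3 Hz) and an occupancy prior
(uniform prior available by flag); the decoder consumes raw integer spike
counts with a Poisson likelihood, computed in log space, and predicts the
centre of the maximum-posterior tile, ties broken toward the lowest
row-major tile index.  Counts rather than sqrt/z rates follow the standard
reconstruction convention.

**Evaluation.**  10 trial sets, each balanced over left/right choices
(per-side size = the smaller side count), 75% train / 25% test per set;
the reported error is the mean over sets.  Downsampling (sizes 4–40 step
4, 5 repetitions) and greedy forward selection reuse the same protocol;
greedy evaluation fixes one seed for all candidate evaluations so the
argmin is well-defined and verifiable by exhaustive re-evaluation.  Error
maps reduce per-trial errors within each tile (max or mean), average over
trials, then over sessions.

## Excursion detection and statistics

At the fine profile, for each of 10 balanced sets the test group is the
bins within 1.5 s after reward delivery in the selected trials and the
training group is every other in-trial bin.  A trial is flagged when the
maximum per-bin error in its window exceeds 70 cm in any set that tested
it (per-set flag fractions are also reported).  "Reward delivery" is anchored at target-feeder
activation by default (`anchor="offset"` switches to the feeder
off-set; both anchors are defensible readings of "reward delivery").  The episode around a flagged
window's peak is the maximal contiguous run of bins with error ≥ 35 cm
(half the flag threshold) containing the peak bin — a hysteresis rule
chosen here because only the flag threshold and the resulting duration
distribution are specified; it is exposed in config.  The endpoint is the
decoded position at peak error, labelled by the nearest feeder within the
zone radius.

Endpoint concentration is tested by Pearson χ² of endpoint counts over k
equal-length skeleton segments against a uniform null (k defaults to the
number of 4×3 cm tiles touched by the skeleton); this uniform null and its
binning are conventions of this package — χ² magnitudes are therefore not
comparable across implementations that bin differently.  The preference analysis regresses
the fraction of forced-trial excursion events at R (among forced-trial
events at either target feeder) on the revealed preference for R (fraction
of free choices to R), by ordinary least squares over sessions.

The multi-session preference study (`counterbalanced_study`) varies the
large-reward side, choice temperature and effort weight across sessions —
mirroring counterbalancing across animals/sessions — and uses 2 schedule
repeats (192 trials, matching the 162–256 trials a typical behavioural session yields).  For this
statistical study the per-session event lists come from the generator's
injection log (`events_from_injections`); the detector's agreement with
that log (recall, false-positive rate, durations) is established separately
on single sessions, where running the network detector is affordable.
Bayesian reconstruction cannot substitute here: on 20 ms count bins its
bin-to-bin jitter alone exceeds 70 cm in nearly every window, so the
window-max statistic requires the smoothed-rate network decoder.

## Cell informativeness

**Reward/choice (Lasso).**  Features are per-trial mean rates in the 1.5 s
post-reward window at the target feeder; labels are reward level or chosen
side.  For each of 50 class-balanced trial sets (75/25 split), an
L1-regularized logistic regression is selected over a penalty path by
5-fold cross-validation, keeping only path points with ≤ 20 nonzero
weights.  Features are standardized per set (training statistics) so the
penalty treats cells with different rate scales evenly.  The path point is
chosen by the one-standard-error rule — the sparsest model within one SE of
the best cross-validated accuracy — rather than the raw argmax: with an
anchor signal present both choices agree, but under label-free data the
argmax systematically prefers large noise-fitting models and would report
spurious selections.  Sets whose winning model scores below 0.5 on the
held-out quarter are discarded as degenerate.  A cell's selection
frequency over sets maps to categories: ≤ 30% not informative, 30–70%
relatively informative, > 70% very informative.  Note the frequency
measures *stability of selection within the session*: a chance correlation
present in the session's trials is repeatedly re-selected, so the
appropriate null aggregates across independently shuffled labelings.

**Excursion-related cells.**  Per detection set, excursion samples are the
bins in the 80 ms window centred on each event's peak; non-excursion
samples are the remaining bins of that set's post-reward windows.  Rates
are square-root transformed and compared per unit by a two-sided Welch t
test at α = 0.01 (strict inequality; the source states only "a t-test"),
with selection frequencies split by occupied feeder and categorized as
above.

## Null models and pattern analyses

**Jitter** shifts each spike by a zero-mean Gaussian with variance 25% of
the unit's ISI variance; the variance is computed, and the shifts applied,
in the concatenated-window coordinate of each feeder set (gaps between
windows excised).  Computing ISI variance on raw timestamps would include
multi-second inter-trial gaps and produce second-scale shifts that destroy
all structure; the excised coordinate yields the intended tens-of-ms
perturbation.  Spike counts are conserved exactly; units with fewer than 2
spikes in a set are left alone.  **ISI shuffle** permutes a unit's
inter-spike intervals in the concatenated-window coordinate, preserving
the first spike, the ISI multiset and the total span exactly.  For the
shuffled classifier surrogate the windows are extended by the 5 σ kernel
support before shuffling, so unshuffled spikes adjacent to a window cannot
bleed label information into its edge bins through the smoothing kernel —
without the halo the surrogate retains above-chance accuracy for a purely
numerical reason.

**Feeder classifier.**  Samples are fine-profile bins within 750 ms after
the centre-feeder off-set (label C) and 1500 ms after the target-feeder
off-set (label L/R).  The classifier is the decoder trunk with a 3-way
softmax output, trained on original data from a class-balanced trial
subset and tested on held-out trials of each variant (original, jittered,
shuffled), 10 repetitions; confusion matrices are row-normalized and
averaged.  **Excursion-pattern discrimination** builds per-trial vectors
(mean rates over 0–1.5 s after feeder close for non-excursion trials, over
the 100 ms peak-centred window for excursion trials) in classes A/A'/B/B'
by feeder and excursion status; A vs A' and B vs B' use a decision tree
with ≤ 10 splits, A' vs B' a linear-kernel SVM, each scored by
cross-validated ROC AUC with class imbalance left intact.  **LDA** gives a
two-component discriminant projection of feeder-window patterns with a
silhouette separation score; singular scatter falls back to a small-ridge
eigen solver.

## Problem sizes and reproducibility

The reference synthetic session uses 40 units and one 96-trial schedule
pass (~870 s); recovery experiments use 12 injected excursion trials; the
preference study uses 7 counterbalanced sessions of 192 trials; the test
suite's smoke fixtures use 8 units and 2 blocks.  All stochastic
operations require an explicit integer seed; stage seeds are derived with
`numpy.random.SeedSequence.spawn`, so any stage's draw count can change
without perturbing the others, and end-to-end pipeline runs are
bit-reproducible for a fixed config.

## Known limitations

* The decoder's absolute error and the 36%-style RMSE gap between methods
  are properties of the generator's tuning statistics; only directional
  and threshold properties are asserted.
* The χ² endpoint null and the episode-boundary rule are reconstructions
  of underspecified steps and are flagged as such in config/docstrings.
* The excursion blend is a stationary rate mixture; analyses that would
  distinguish replay-like sequential structure from a shift cannot be
  exercised on this generator (sequence scoring is out of scope).
* Lasso selection frequency quantifies within-session stability, not
  false-discovery-controlled significance.
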