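# Methods

`smbuffers` implements the analysis suite for studying *structured memory
buffers* (SMBs): populations of frontal-cortex-like neurons that tile
progress to goal and fire at fixed task-space lags from specific behavioural
steps in multi-goal sequence tasks. Because real recordings are not bundled,
every stage is validated by parameter recovery on synthetic data with known
ground truth. This note describes the model, the generator, the numerical
choices and what passing tests do and do not establish.

## Task geometry and coordinates

The task is a loop of 4 (ABCD) or 5 (ABCDE) rewarded locations on a 3x3 grid
maze (nodes 1-9, row-major; edges along cardinal directions only). A *trial*
runs from one reward at location a to the next; each inter-reward interval is
a *state*. Task angle places a full trial on [0, 360): state k occupies
[k·s, (k+1)·s) with s = 360/periodicity, and *goal progress* is the elapsed
fraction of the inter-reward time, binned into thirds (operational) or fifths
(encoding model). Activity is time-normalized to 90 bins per state (360 bins
per ABCD trial, 450 per ABCDE trial) by counting spikes in equal-duration
sub-intervals of each state and dividing by the sub-interval duration — a
mass-preserving resampling (binning happens during warping, not before).
Curves are smoothed with a circular Gaussian (sigma 10 degrees, 8-sigma
support so the smoother matches an explicit wrapped convolution to machine
precision).

## The generative model

A buffer neuron is defined by an anchor (goal-progress bin x node), a lag
lambda in [0, 360), tuning concentrations and rates. Its intensity is

    rate(t) = baseline + peak · gain(t) ·
              exp(k_task (cos(Delta(t) − lambda) − 1)) ·
              exp(k_gp (cos(phi(t) − phi_pref) − 1))

where Delta is the task angle elapsed since the most recent anchor visit
(visit = first task-space bin at which the animal occupies the anchor's node
during the anchor's goal-progress bin; consecutive bins collapse), phi is the
goal-progress phase and phi_pref is the phase at which the bump arrives
(anchor-bin centre + lambda, modulo the state span) — so lagged cells retain
goal-progress tuning. Because the von Mises bump is periodic in Delta, the
buffer re-activates every full trial after a visit, i.e. the bump keeps
circulating on the loop. Spikes are drawn as an inhomogeneous Poisson process
on a 10-ms grid. `gain(t)` is an optional step function used by the
choice-prediction experiment to couple bump amplitude to upcoming behaviour.

Defaults and why:

- **Behaviour**: dwell times are lognormal, mean 1.0 s (cv 0.8) per node and
  2.5 s at rewards, giving trials of roughly 15-30 s with substantial
  variability, in the range of real sessions of this task family.
  Near-metronomic trials would also make circular-shift nulls degenerate.
  Policy optimality epsilon = 0.97 for recording-stage behaviour (well above
  the 70% training criterion), with optional step-choice stickiness to
  emulate habits.
- **Tuning**: the high-SNR recovery regime uses peak 20 Hz, baseline 0.2 Hz,
  k_task = 20 (bump half-width ~25 degrees) and k_gp = 0.5. The weak k_gp
  makes the bump *visit-locked*: its task position is exactly lambda after
  each visit. Strong gp-pinning instead pulls the bump toward a fixed
  within-state phase, which systematically favours a phase-locked alias of
  the true anchor; weak pinning is also what the buffer model itself
  describes (the bump is paced from the anchor visit).
- **Offline activity**: a latent phase performs a random walk
  (150 deg·s^-1/2) that wraps on the ring or reflects at the ends of the
  delay line; member neurons are tuned to the phase at their lag (k = 1.5,
  wide enough that coactivity decays over the full line rather than
  saturating at one bin of separation). The line extends 90 degrees beyond
  the outermost lags so end neurons' fields are not truncated (truncation
  depresses their firing probability and tilts the pairwise-correlation
  floor, mimicking a wrap). Identical dynamics up to the boundary rule keep
  the ring/delay-line comparison clean. An initial design used discrete
  forward sweeps for the delay line; with 250-ms coactivity bins any sweep
  fast enough to produce coincidences saturates within ~40 degrees of
  separation, making the upper half of the forward-distance curve flat
  instead of falling, so the diffusion formulation was adopted.

## Analyses

**Encoding model.** Leave-one-(task x state)-out: training periods provide
the neuron's mean rate per goal-progress fifth, per node (edges excluded) and
per place-next-place conjunction (24 levels, the lenient trajectory screen);
the held-out period is regressed on these training-mean regressors plus
locomotion confounds (transition rate smoothed over 1 s, its derivative, time
from reward, Manhattan distance to goal). Regressors and target are z-scored
within each fold so fold coefficients live on a correlation scale — without
this, folds in which a regressor is nearly constant (e.g. the field node is
never visited in the held-out state) produce unbounded coefficients that
dominate the average. Significance requires (1) the mean coefficient to
exceed the 95th percentile of 100 permutations and (2) cross-task level-map
correlations significantly above zero. The permutation shifts the raw spike
train circularly in *time* (uniform on 5-95% of the session) and re-bins it:
shifting the already-normalized array would re-align any task-periodic
variable whenever the shift approximates a multiple of the state span,
destroying the null. The same machinery drives the cross-structure
(five-state to four-state) generalization test.

**State tuning.** Per-trial per-state peak rates are row-z-scored; the
preferred state is selected on the odd trials and its z-scores are t-tested
against zero on the even trials. Selecting and testing on the same trials
inflates the false-positive rate to ~18% (the argmax of four zero-mean
averages is positively biased); the split-half keeps it at the nominal 5%.

**Rotation, coherence, clustering.** Cross-task angles come from an
exhaustive 10-degree-grid rotation search maximizing Pearson correlation
(FFT cross-power implementation, verified against brute force; ties break
toward the smallest absolute angle). Generalizing/coherent means staying
within an inclusive 45-degree window of zero across all comparisons, giving
the analytic chance (1/4)^m for m comparisons. Clustering embeds the
pairwise incoherence matrix 1 − cos(max angle change) with t-SNE (perplexity
5, seeded) and cuts an agglomerative tree at a fixed distance threshold
(default 300, matched to large populations; the threshold is a scale
parameter of the embedding and should be reduced for populations of a few
dozen neurons). The permutation control preserves reference-task tuning and
goal-progress structure but randomizes whole-state remapping.

**Manifold.** Neuron-task z-scored mean curves are stacked as features and
the task-position bins embedded with UMAP (3 components, cosine metric, 50
neighbours, min_dist 0.6). The quantified claim is only the distance
contrast: across-state bin pairs sharing a goal-progress third are closer
than pairs in different thirds, with a floor control that shuffles state
identity across trials *before* averaging and re-embeds.

**Anchoring.** Method 1 re-aligns activity to every candidate anchor's
visits (one trial-length window per visit, averaged, smoothed), computes
rotation distances 1 − cos(theta) between tasks, and picks the (reference
training task, anchor) pair minimizing the mean distance over training
comparisons; the held-out task validates the alignment (45-degree window)
and the test-train correlation is evaluated in the neuron's preferred
goal-progress bin. The per-reference-task mean table has
N_train x N_anchors entries (each averaging that task's N_train − 1
comparisons). Method 2 computes spatial maps of current firing against the
node occupied 0-330 degrees earlier (12 lags of 30 degrees; the lag count is
configurable, and a 10-degree grid sharpens the map-peak location), selects
the lag maximizing cross-task map correlation on training tasks, and
validates on the held-out task. Method 3 fits an elastic net (equal L1:L2,
alpha 0.01; the Poisson/log-link variant uses alpha 1) on binary indicators
"the most recent visit to anchor a fell in lag window L". The last-visit
(one-hot per anchor) encoding mirrors the buffer's reset-at-visit dynamics;
window-occurrence indicators overlap for densely visited anchors and dilute
long lags badly. Per lag, one reference anchor level is dropped — at every
moment some behavioural step was occupied L degrees ago, so the full set of
27 indicators per lag is (near-)collinear — giving 26 x 12 = 312 columns for
the standard configuration. Because a real-valued lag straddles two adjacent
windows, anchor scores pool positive coefficients over circularly adjacent
lag pairs. Fitting and evaluation are restricted to the preferred
goal-progress bin.

**Recovery ground truth.** Anchors are sampled from behavioural steps with
at least 5 visits in most tasks and at least one visit in every task, and
without a *same-node alias*: when the animal reliably dwells through a
goal-progress boundary, the same node's adjacent bins are visited at a fixed
30-degree offset in every task, and no anchoring method can tell such a pair
apart even in principle. Lags keep the bump's goal-progress phase 5
within-state degrees away from bin boundaries so the preferred bin is well
defined. Method agreement is scored per what each method outputs: Methods 1
and 3 must name the same (goal-progress bin, node) conjunction; Method 2
contributes its map-peak location and a lag within one 30-degree bin of
Method 1's.

**Choice prediction.** Candidate events are entries into a conjunction one
maze step before the anchor (adjacent node, previous goal-progress bin,
wrapping into the preceding state); the outcome is whether the next step
enters the anchor conjunction. The bump regressor is the mean rate in the
most recent [lambda, lambda + 30 deg) window after the last anchor visit
*that ends before the event* — windows reaching past the event would leak
post-outcome activity, which is also why the random-control window samples a
task phase away from the bump phase. Choice history (anchor visited in each
of the 10 previous trials) is collapsed through an exponential kernel fitted
to a first-pass 10-column logistic regression (flagged fallback to the raw
columns if the fit is non-decaying). Per-task logistic fits are unpenalized;
separation is detected by a coefficient-magnitude cap and such tasks are
excluded from the population t-test. The synthetic coupled condition
multiplies the bump by (1 + 2·outcome) between consecutive events; the
habitual condition uses sticky path choices with no neural coupling.

**Offline structure.** Coactivity is the zero-lag Pearson correlation of
250-ms binned counts. Pair geometry uses forward distance |lambda_j −
lambda_i| and circular distance min(f, 360 − f). The state-space regression
includes both distances plus goal-progress distance and awake spatial-map
correlation; the within- vs between-anchor comparison of circular
coefficients uses a normal approximation on the analytic standard errors
(the source analysis treats pairs as units, so this is approximate and
labelled as such). The V-curve statistic is the correlation of coactivity
with forward distance separately below and above 180 degrees.

## Degenerate inputs and tie rules

Zero-variance curves make rotations undefined (NaN, excluded); constant
goal-progress profiles are excluded from consistency; flat neurons break
goal-progress ties toward the lowest bin; Method 2 lag ties break toward the
earliest lag; single-cluster days return a NaN silhouette sentinel;
candidate events with no prior anchor visit, and logistic fits with one
outcome class or separation, are dropped with flags.

## Problem sizes

Default experiment sizes are chosen so a full validation runs on a laptop
core in minutes: recovery uses 40 neurons, 6 tasks of 25 trials; choice
prediction 50 tasks of 40 trials per condition; offline discrimination 20
sessions of 240 s; encoding-model calibration 200 structureless neurons over
3 tasks of 10 trials with 100 permutations each.

## What passing tests show — and what they do not

The synthetic generator shares the analysis-side task-angle conventions by
construction, uses Poisson spiking, unimodal single-anchor tuning, and
behaviour that is more stereotyped and stationary than a real animal's. Real
recordings add multi-peaked spatial anchors, mixed selectivity, slow
nonstationarity, spike-sorting noise and behavioural drift; recovery rates
here are therefore upper bounds on what the same pipeline would achieve on
real data, and the calibration results (false-positive rates, analytic
chance levels) are the parts that transfer directly. Behavioural steps that
perfectly co-occur remain unidentifiable for any method; the package reports
them rather than resolving them. Multi-anchor mixtures per neuron are out of
scope (single best anchors only).
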