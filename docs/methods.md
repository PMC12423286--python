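# Methods

This note documents the models, conventions, parameters and numerical
choices behind `timecourt`, and what the synthetic-data tests do and do
not establish about real recordings.

## Task model and time conventions

A trial is: ready period (600 ms), pre-cue gap (300 ms), cue (600 ms),
then a wait of the cued target duration and a response ("go") window of
equal length. All stored times are **ms relative to cue onset**;
behavioral response times are measured from cue offset (wait onset),
which is how the task defines them. All bins and windows are half-open
`[start, end)`, so a spike at a window edge is counted exactly once.

Outcome labeling (`preprocessing.label_trial`): a response is *correct*
from 80 % of the target duration (1200/2400/4800 ms) to the end of the
response window (2 × duration); *early error* between 1200 ms and the
80 % point (possible only for the two longer targets); *late error* if no
response falls inside the window; anything before 1200 ms is an *abort*
(including strategic opt-outs on the longest duration). Neuron inclusion
requires ≥ 8 correct trials per cue and ≥ 0.5 Hz mean rate over the
2100 ms composite pre-cue + cue + early-wait window; both thresholds are
inclusive, and the rate is computed on correct trials only (the labeled
subset every analysis uses unless stated otherwise — the alternative,
using all trials, is not materially different for any synthetic
population we generate but is not what the downstream selection assumes).

## Synthetic sessions

The generator is the package's reference input: it produces sessions with
the statistical structure the analyses assume, plus full ground truth.

**Behavior.** Response times for target `d` are Gaussian with mean
`d·(1 + mean_offset_fraction)` and SD `weber_fraction × mean` — scalar
timing by construction — truncated at zero by resampling (clipping would
pile mass at 0 and bimodalize the histograms). Defaults:
`weber_fraction = 0.2` and `mean_offset_fraction = 0.1`, the magnitudes a
trained subject shows on this task (fitted σ/center ratios around 0.17 to
0.21, centers just past the target); `optout_prob = 0.3` of aborting a
longest-duration trial within 400 ms of the wait, matching the observed
strategy of skipping long waits to reach a likely shorter next trial; a
small `lapse_prob = 0.05` of late errors so error-trial analyses have
data. A delayed-retry engine repeats cues until the requested number of
correct trials per cue exists; error trials stay in the table.

**Spikes.** Each neuron has a ground-truth rate function of time,
condition and protocol (archetypes: duration-tuned, Gaussian time field,
linear/exponential/sigmoidal ramps that reach baseline + gain at the
target time, stretched templates whose profile for duration `d` is the
reference template scaled by `d/d_ref`, protocol-modulated, untuned).
Condition-dependent gains apply from cue onset (the moment the cue
discloses the condition); wait-anchored shapes unfold from cue offset.
Emission is an inhomogeneous Poisson process sampled by thinning on a
1 ms rate grid. Poisson is the simplest process consistent with
everything the pipeline measures; spike-count dispersion is an assumption
of the generator, not a measured property, and an overdispersion knob is
deliberately deferred. No inter-neuron correlation exists beyond shared
rate profiles, and one synthetic "session" records every neuron on every
trial — the decoders still resample trials independently per neuron, so
the pseudopopulation convention matches the pooled-across-sessions case.

What passing recovery tests therefore shows: the *estimators* are
correct — they recover the parameters of data that satisfy their own
assumptions at realistic firing rates and trial counts. What they do not
show: robustness to non-Poisson variability, correlated noise, drift, or
selection effects present in real recordings.

## Behavior quantification

RT histograms use 200 ms bins from 0. The Gaussian fit fixes its center
at the modal bin's center (ties broken to the earliest bin,
deterministically) and fits amplitude and σ by least squares on the raw
counts; r² = 1 − SS_res/SS_tot. Fixing the center keeps σ robust to
early low-frequency responses. On the longest duration the first two bins
(400 ms) are excluded before fitting, since sub-400 ms responses there
are opt-outs, not estimates; the exclusion is configurable. The scalar
summary reports (center, σ) pairs sorted by duration and flags whether σ
increases strictly with the center.

## Single-unit statistics

**Selectivity.** Per neuron and per alignment window (1200 ms after cue
offset; 1200 ms before response onset), a two-way ANOVA with target
duration and stimulus protocol as factors, α = 0.01. Type II sums of
squares via statsmodels: identical to the classical decomposition when
balanced, and the appropriate main-effect test for the unbalanced designs
the delayed-retry protocol produces (no interaction assumed when testing
main effects). A *time neuron* has a significant duration effect and no
protocol or interaction effect. Preferred duration is the argmax of the
marginal means; ties break to the shorter duration with an explicit flag.

**Tuning.** Curves are min-max normalized to 0–100 %; width is the
weighted SD of the duration axis with normalized responses as weights.
Monotonicity is defined for extreme-preferring neurons only
(shortest-preferring: rates non-strictly decreasing; longest-preferring:
non-strictly increasing) — non-strict because equality is not evidence
against an ordered code.

**Trend test.** Jonckheere–Terpstra: the sum of pairwise Mann-Whitney
counts over ordered group pairs, ties counted ½. The normal approximation
uses the tie-corrected variance and a continuity correction of ½ (the
statistic is discrete); for total n ≤ 12 the exact one-sided p is
computed by enumerating every distinct assignment of the pooled sample to
the group sizes.

**Ramping.** A neuron is *increasing* when the peak of its binned wait
profile falls in the final 600 ms before the response and a paired t-test
(initial 600 ms after cue offset vs final 600 ms before response,
α = 0.05) is significant with final > initial. Linear, exponential
(a·e^{bt}+c) and sigmoidal (L/(1+e^{−k(t−t₀)})+c) models are fit to the
100 ms-binned, min-max-normalized profile by bounded least squares with 5
random multistarts (the functional forms and bounds are minimal standard
choices). Significance compares each model's r² to the 95th percentile of
that neuron's own 1000 bin-shuffled r² values for the same model — the
per-neuron null is the conservative reading of "better than chance".
Fits are per duration on cue-offset-aligned activity (configurable);
concatenating durations would conflate scaling with ramping.

**Temporal scaling.** Profiles are 10 ms-binned samples anchored at the
wait onset (grid points k·10 ms, so an exact integer stretch maps grid
onto grid and the true factor attains MSE exactly 0). The long profile's
time axis is compressed by each candidate factor, linearly interpolated
onto the short profile's grid, and scored by MSE over the overlapping
span; factors leaving < 2 overlapping samples are skipped, ties go to the
smaller factor. The default grid is 0.05–3.0 in 0.05 steps — fine enough
to contain the analytic expectations 0.25, 0.5 and 1.0 exactly — and a
within-10 %-of-expected flag supports population summaries.

## Decoding

All decoders share one core: linear SVM with one-vs-one multiclass and
fixed C = 1 (the conventional default; configurable), stratified
cross-validation, and **train-only z-scoring** — feature means and SDs
come exclusively from the training rows of each split, zero-variance
features map to 0 (silent neurons stay neutral). Accuracies are percent;
confusion matrices accumulate true × predicted counts over folds and
resamples, and the accuracy recomputed from the pooled confusion equals
the mean per-resample accuracy by construction.

Pseudotrials pair randomly drawn (without replacement) trials across
neurons per class per resample; pairing is uniform because the neurons
were not recorded simultaneously, so no true joint structure exists to
preserve. Across-protocol decoding trains on all pseudotrials of one
protocol and tests on the other's — disjoint by construction, so CV folds
apply only within-protocol. Elapsed-time decoding treats each
(trial, bin) pair as an observation (20 trials × 20 proportional bins =
400 observations; 5-fold CV → 320 train / 80 test), features are
per-neuron min-max-normalized bin rates (then z-scored train-only), and
predicted-bin distributions accumulate per true bin —
resamples × folds × 4 observations per bin per fold. Correct-vs-late-error
decoding trains 2-class (1500 vs 3000 ms) models on correct trials with
10-fold CV and tests every fold on held-out correct trials and on the
late-error set, which is redrawn with replacement each resample (late
errors are rare).

Cross-temporal decoding slides a 200 ms window in 20 ms steps from
pre-cue onset to 1800 ms into the wait; the classifier trained at window
w is tested at every window w′ of the held-out trials, with **w's scaler
applied throughout** (scaling per test window would launder test-time
information into the comparison). Significance uses a cluster permutation
test: pixels where the mean true accuracy exceeds the pixelwise 99th null
percentile form candidate clusters under 4-connectivity (the stricter
standard adjacency), and a cluster is significant when its size exceeds
the 99th percentile of the null maximum-cluster-size distribution. The
bin-stability decoder is the same generalization machinery on the 20
proportional wait bins per duration.

## Population dynamics

**ω² PEV.** Sliding 200 ms windows in 20 ms steps. Each resample draws
exactly 15 trials per duration × protocol cell per neuron — a balanced
design, so a closed-form cell-means decomposition (vectorized over
neurons × windows) applies; it is cross-checked against the statsmodels
route in the tests. ω² = (SS_term − df·MS_error)/(SS_total + MS_error) ×
100 per factor, averaged across neurons, with 20 resamples and 50 label
shuffles per resample (1000 reshuffles) for the baseline. ω² is not
floored at zero: slightly negative values under the null are what makes
the estimator unbiased, and the baseline panel shows them rather than
hiding them.

**Trajectories.** Per duration, the window runs from 900 ms before cue
onset to the earliest-correct point of the wait — spans of 2700, 3900 and
6300 ms computed from the event times themselves. Rates are
trial-averaged at 20 ms resolution, smoothed with a 200 ms-SD Gaussian
kernel (truncated at 5 SD, edge-renormalized so short windows do not
droop), z-scored per neuron on the concatenation across durations (so a
few high-rate neurons cannot dominate), and PCA is fit on that
concatenation: a **common basis**, without which between-condition
distances would be meaningless. Each duration's segment is projected onto
the first three components; component signs are fixed by making each
component's largest-magnitude loading positive, for reproducible plots.
Distances are pointwise 3-D Euclidean norms over the overlapping span of
a pair; amplitude is the distance to the cue-onset state (zero at the
reference by definition); velocity is the distance between consecutive
states divided by the step in seconds, boxcar-smoothed over 5 bins.
Amplitude and velocity are descriptive only.

## Problem sizes and determinism

Every stochastic routine takes a seed or Generator; a single root seed
yields byte-identical sessions and decoder outputs. The test suite and
the acceptance script run reduced-but-honest problem sizes chosen so each
check still has the statistical power it needs: e.g. 50 profiles for the
scaling recovery, a 200-neuron population with 500 shuffled resamples for
chance calibration (standard error ≈ 0.2 points), 10–12 correct trials
per cue for recovery sessions, and reduced shuffle counts where a null
distribution only gates a qualitative flag. Full-scale parameters
(1000 resamples, 1000 shuffles) remain the documented defaults of the
library functions.

## Known limitations

- Poisson emission: no overdispersion, refractoriness or bursting.
- No trial-to-trial rate correlations between neurons; noise correlations
  that would degrade pseudopopulation decoding are absent by design.
- The Gaussian-fit center is locked to a 200 ms bin center; sub-bin
  center refinement is deliberately out of scope.
- Cross-validated accuracy under label shuffling is biased slightly below
  nominal chance (a known property of CV nulls with small test sets); the
  shuffle thresholds inherit and correctly account for this, but the
  mean shuffled accuracy should not be expected to equal chance exactly.
- The scaling search assumes profiles are aligned at wait onset; onset
  misalignment masquerades as a scaling failure.
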