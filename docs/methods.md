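# Methods

## Timeline model

A trial is a fixed 4,480 ms reach-and-grasp recording. Video frames
arrive every 40 ms (25 Hz), so a trial holds exactly 112 frames; frame
`k` is identified with its start time `40k` ms. All intervals — phases,
sweet periods, vote windows — are half-open `[start, end)`. This
convention is forced by the frame arithmetic the pipeline relies on:
`[0, 160)` contains 4 frames and `[0, 320)` contains 8, and a partition
of the trial into adjacent windows partitions the frame set.

Three phases segment the trial: reaching `[0, 1020)` ms (hand lift-off
to object contact), early grasping `[1020, 1604)` ms (contact to firm
hold), firm grasping `[1604, 4480)` ms. The boundaries are
cohort-averaged contact times and are configuration constants, not
estimated per trial.

The sEMG decision window is fixed at `[1100, 1400)` ms in the early
grasping phase, imported from prior work on the muscle side; this
package searches only for the *vision* window. At the default 40 ms
decision period the sEMG window contains 7 decision points
(`1120, 1160, …, 1360` ms) — a consequence of the half-open convention
and the 25 Hz stream, not a tunable.

## Sweet-period search

Candidate windows are `[0, e)` for every frame boundary `e`; anchoring
at 0 ms encodes the design goal of classifying as early in the reach as
possible. Each window is scored by the mean of the cohort valid-frame
proportion curve over its frames; points with an empty denominator are
excluded from the mean (and a window with only undefined points scores
NaN). The selected window is the highest-scoring one with at least
`min_window_frames` frames (default 5), ties broken toward the shorter
window. The minimum-length constraint exists because a very short
window can top the score while casting too few votes for a reliable
plurality — the 4-frame `[0, 160)` window is the canonical rejected
case. `anchored_window_scores` always reports every candidate's score
so a selection can be audited.

The search metric is deliberately valid-frame proportion, not
classification accuracy: per-frame vision accuracy is roughly flat over
the trial, so the binding constraint on an early vote is evidence
*availability*, not evidence quality.

## Vote and fusion model

Each modality's sweet period is condensed by plurality vote. The
confidence is the winning label's share of votes actually cast — for
vision the denominator is the number of *valid* frames in the window,
never the window length, which is what makes the sparse-vision bound
work: with at most `v` valid frames and at least one misclassified, the
confidence is at most `(v-1)/v` (75% at `v=4`, verified against
exhaustive enumeration of all vote configurations).

Integration keeps the modality with the strictly higher confidence.
Two tie rules are needed that the max-confidence idea itself does not
fix, and both are package decisions: an exact confidence tie goes to
sEMG (the always-available modality is treated as the default), and a
tie inside a vote goes to the lowest gesture ID (determinism across
runs and trial orderings). Vision may abstain — no valid frame in the
window — in which case sEMG decides by construction.

## Synthetic cohort generator

The generator emulates a 30-subject study: each subject performs the 10
taxonomy gestures on their listed objects (30 gesture-object pairs in
total; one gesture lists four objects and one lists two) with 4
repetitions — 120 trials per subject, 3,600 in all. It simulates
*classifier outputs only*: per-frame validity flags and predicted
labels, never images or waveforms.

**Frame validity.** A piecewise-linear probability curve: baseline 0.47
at 0 ms, peak 0.58 at 160 ms (the subject fixates the object before
moving, then the reaching hand progressively occludes it), linear
decline to a 0.08 floor at 1,604 ms, constant floor during firm
grasping. A per-trial shift drawn uniformly from ±120 ms models
subjects touching the object at different moments; the marginal
(jitter-averaged) curve is available as `expected_validity` and is the
quantity the empirical cohort curve estimates. Baseline and peak were
calibrated once so that the expected mean validity over `[0, 320)` is
≈0.53 and `[0, 320)` is the best admissible window of the expected
curve. The top window scores differ by under 0.001, so on a 900-trial
fold the realised selection alternates between `[0, 320)` and
`[0, 360)` — the search operates in a genuine near-tie regime.
Frame validities are independent across frames given the curve; an
optional first-order persistence parameter (`validity_persistence`,
default 0) adds run-length correlation for robustness studies.

**Vision predictions.** Among valid frames, the predicted gesture is
correct with probability 0.92 and the predicted object with 0.97,
independently per frame; errors are uniform over the 9 (resp. 17)
wrong labels, or follow an optional per-gesture confusion table.
Gesture and object predictions are drawn independently — no joint error
statistics are available to calibrate a coupling.

**sEMG stream.** Labels at 40 ms decision points across the whole trial
(no validity concept). The error model is two-level: a per-trial
dominant label, correct with probability 0.855, which each decision
point votes with probability 0.9 (stray votes uniform over the other 9
labels). A per-point i.i.d. error model cannot jointly produce the two
properties a realistic muscle stream has — moderate trial-level accuracy
(~85.5%) *and* plurality confidence typically above 75% — because i.i.d.
errors at that accuracy scatter the vote. The two-level model gets both:
the dominant label virtually always wins the 7-point window, and its
confidence is `Binomial(7, 0.9)/7`, above 75% in ~85% of trials.

**Seeding.** Every trial draws from its own RNG stream derived from
(master seed, subject, gesture, taxonomy pair index, repetition) via
`numpy` `SeedSequence`. Cohorts are therefore reproducible,
generation-order independent, and any single trial can be regenerated
in isolation. The draw order inside a trial (jitter, validity, gesture
predictions, object predictions, sEMG dominant, sEMG votes) is fixed.

## Evaluation harness

Leave-one-repetition-out: fold `r` tests all trials of repetition `r`.
Nothing is trained in the synthetic pipeline, but the train/test
separation is preserved — each fold's vision sweet period is selected
from its training repetitions only (configurable to whole-cohort
selection via `sweet_period_scope: all`) — so the harness runs
unchanged on real classifier exports where the upstream networks *are*
fold-specific. Pooled accuracy counts each trial once across folds and
equals the trial-weighted mean of fold accuracies.

`vision_only` accuracy is reported under both defensible denominators:
among trials with a present vision decision (primary), and over all
trials with abstentions counted as errors. The two differ exactly by
the vision abstention rate, which the report also exposes
(`n_vision_present`). Note that trial-level vision plurality accuracy
(~0.99 at the defaults) is substantially higher than the per-frame
accuracy (0.92) because the vote averages out independent frame errors;
the per-frame figure is recovered by `window_mean_accuracy`.

## Numerical and degenerate-input choices

- Curve points with zero denominator (e.g. no valid frame at a time
  point) are explicit NaNs, excluded from window means and plots, never
  imputed or zeroed.
- `find_sweet_period` uses first-maximum selection on the cumulative
  mean, which implements the shorter-window tie-break exactly.
- An empty vote sequence yields an *absent* decision (confidence 0 by
  convention), distinct from any present decision, whose confidence is
  strictly positive.
- A cohort file encodes "no prediction" as the sentinel token `none`;
  an empty cell is a format error, so truncation cannot be mistaken
  for invalidity.
- sEMG windows with no decision points raise (a malformed trial), while
  vision windows with no valid frames are a normal abstention.

## What the tests do and do not show

The statistical tests (parameter recovery within binomial error at
3,600 trials, the accuracy ordering across 10 seeds, confidence
distributions) validate the *pipeline arithmetic* against the
generator's known ground truth at the study's scale; the experiment
driver completes in seconds, so no scaled-down problem sizes were
needed. They do not validate the generator against real grasp data: real
frame validity is temporally correlated (occlusion is an episode, not a
coin flip), vision gesture/object errors are coupled through the
classifier, sEMG accuracy varies over the trial and across subjects, and
real trials vary in length. Conclusions about real cohorts require
running the same pipeline on real classifier exports through
`read_cohort`.

## Known limitations

- Only anchored `[0, e)` windows are searched; a free-start search is
  out of scope by design.
- The sEMG sweet period is a constant, not searched.
- No probabilistic (soft-score) fusion; only vote fractions.
- The generator's per-subject behaviour is exchangeable — no subject
  effects beyond the trial jitter.
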