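# Methods

This note records the analysis model, its parameters and conventions, what
the synthetic cohorts do and do not emulate, and the choices made where the
design was genuinely open.

## Stimulus design model

The experiment is 8 conversations × 10 utterances (6 filler + 4 target,
one target per condition of the 2×2 lexicosyntactic × prosodic
completeness design). All timing is in integer milliseconds from
conversation onset with half-open intervals `[onset, offset)`. Consecutive
utterances are separated by exactly 500 ms of silence; the silence
following a target utterance is the measured target transition. Constraints
enforced by `generate_design` and checked by `validate_design`:

* 32 targets total — 8 per condition, 16 per speaker, and 4 per speaker
  within each condition (each conversation carries 2 left / 2 right
  targets);
* targets after which the utterance is lexicosyntactically incomplete are
  always followed by the same speaker continuing; lexicosyntactically
  complete targets are followed by a speaker change in exactly half of
  their 8 occurrences (the 50% balance is enforced per condition at the
  experiment level — the conversation-level reading is not required and
  not imposed);
* 5–7 speaker transitions per conversation; conversation duration
  30 s (accepted band 29–31 s);
* condition order over target positions is counterbalanced with two
  shuffled cyclic Latin squares, so each condition occupies each serial
  position exactly twice across the 8 conversations.

Free quantities are drawn per seed: utterance durations uniform 1.5–3.5 s
rescaled so each conversation is exactly 30 s including silences; target
slots are four mutually non-adjacent positions among utterance slots 2–9,
so every target is preceded by context and followed by an utterance.
Generation is constraint-guided sampling with global quota tracking and a
retry loop; every emitted design passes the full validator.

## Gaze ingestion and AOI resolution

Tracker exports are delimited tables (50 or 120 Hz; the rate is inferred
from the median inter-sample interval and never used downstream — all
logic runs on milliseconds). A sample is **valid** when at least one eye
carries a valid code (configurable per dialect; default codes {0, 1}
valid, as in common binocular exports). AOI resolution is total:
OFFSCREEN for invalid/missing/out-of-bounds samples, LEFT/RIGHT inside the
closed puppet rectangles, OTHER elsewhere on screen. The puppet rectangles
(x ∈ [0.02, 0.47] and [0.53, 0.98], y ∈ [0.10, 0.90] in normalized
coordinates) are a stated convention — AOI geometry is not dictated by the
method, only that the two regions be disjoint screen halves. Samples with
valid flags but missing coordinates resolve to OFFSCREEN: they cannot
support an AOI claim.

## Exclusions

A trial is excluded when on-screen attention covers < 75% of trial
duration (strict: exactly 75% is kept); a participant is dropped entirely
after more than four excluded trials. Attention is measured on the time
axis: each sample carries the interval to the next sample as dwell, the
last sample the median interval. Only tracker-valid on-screen time counts
as attended — whether untracked-but-on-screen time should count is
genuinely ambiguous; this implementation treats validity as a precondition
and flags that as an assumption. Equipment-failure exclusions are an
input-level drop list, never computed from the data.

## Switch detection

Fixations are maximal constant-AOI dwell runs; same-AOI runs separated by
an intervening run ≤ 75 ms (≈ 1 sample at 50 Hz; tracker recovery is
faster than 100 ms) are merged, with the gap absorbed. The analysis window
is `[silence_onset − lead, silence_offset + lead]` with lead 300 ms
(toddlers) / 200 ms (adults), clipped to the conversation; the window
length itself is a convention chosen to honor a silence-centered window
while containing the criterion-3 deadline `silence_offset + lead`.
Criterion 1 is satisfied by a prior-speaker fixation ≥ 100 ms overlapping
the pre-silence part of the window (a stricter covers-the-final-100 ms
reading is available via `strict_prior_end`). Criterion 3 applies to the
onset of the responder fixation — "initiated" — because AOI streams carry
no saccade velocities; only the onset must precede the deadline, the
fixation may extend past the window. The response turn is taken to start
at the silence offset for switch and continuation targets alike. The
detector is equivalent to a literal search over all (F1, F2) fixation
pairs; internally it uses the earliest eligible F1 offset, which is
sufficient because any pair that works at all works with that F1.

## Chance baseline and correction

For each conversation × group, the four analysis windows are re-placed 100
times, each start uniform over `[0, duration − window_length]`, keeping
durations, the group-lead geometry, and the original target's
prior/responder roles. Shuffled windows may overlap each other and real
silences — redistribution is unconstrained. The per-target baseline is the
mean detection rate over the 100 replicates; `corrected = actual −
baseline`. By default one placement set is drawn per conversation × group
and reused across participants (100 shuffled versions of the original
window placement); per-participant placements are available and are used
in the null-calibration study, where they make participant means
independent so the participant-level SEM is a valid Monte-Carlo standard
error of the grand mean. Whether placements were originally shared or
per-participant is not documented in the method this reimplements; both
estimate the same chance rate.

## Mixed-model suite

All models regress corrected values on −1/+1 contrast-coded two-level
factors with crossed random intercepts for subject and item, one item per
target utterance (32 items). Estimation is REML via `statsmodels` MixedLM
with variance components; the Powell optimizer is used because on these
problems — variance components frequently near the zero boundary — it
reproduces lme4's REML optimum where gradient-based optimizers stall
(cross-checked against lme4 in the test suite). Degenerate subsets fall
back along powell → Nelder-Mead → CG and are flagged (`converged`,
`singular`) rather than raised. Significance is the two-sided Wald
convention |z| > 1.96 at α = 0.05; no multiple-testing correction is
applied, and no p-values beyond that rule are computed. The suite:
full factorial SYN × PROS × AGE; the two partially complete conditions
(condition × age); the +SYN subset (prosody × age); the +SYN subset with
speaker change and all interactions (speaker change is undefined for −SYN
items, which are always continuations); and first-two / last-two-trials
refits of the main model, "trials" read as the first/last two
conversations in presentation order. Items with ambiguous prosodic
contours can be dropped via an exclusion list; the default keeps all
items. Condition summaries report mean ± SEM of actual, baseline, and
corrected values per condition × group, with SEM over participant means
(participant-level variability); a per-observation option exists.

## Synthetic cohorts

The generator emulates the viewing behavior the analysis assumes, not
vision or comprehension:

* **Background gaze** — a renewal process with exponential dwells (mean
  1500 ms): at each renewal the gaze moves to the current speaker with
  probability `follow_bias` (default 0.85), otherwise to an AOI drawn from
  a symmetric transition matrix (occasional OTHER/OFFSCREEN excursions).
  Gaze also re-evaluates whenever speakership changes. In the pure
  background regime (`follow_bias = 0`) the initial AOI is drawn from the
  chain's stationary distribution so the process is stationary from t = 0
  and chance-rate estimates carry no trial-start edge effect.
* **Reactive following** of a new speaker lags turn onset by a latency
  floored just above the group's anticipation lead — the lead *is* the
  minimum gaze-planning time, so purely reactive shifts can never be
  scored anticipatory. This is what makes the zero-noise closed loop
  exact.
* **Anticipatory glances** — at each target, with the condition's
  propensity, a responder glance (≥ 150 ms) launches at silence onset plus
  a group latency draw (toddler draws floored at the 300 ms planning
  minimum). Late draws are kept: they become intended-but-late switches
  scored 0, preserving a realistic miss rate. Ground truth per target is
  "glance launched and its first on-grid sample at or before the
  deadline"; with noise off, the detector reproduces these labels exactly
  (tested).
* **Noise** — per-sample binocular dropout (toddlers 8%, adults 3% by
  default), single-eye dropout (10%, which the at-least-one-eye rule must
  absorb), and Poisson off-screen attention lapses.

Default propensities (0.55 / 0.40 / 0.25 / 0.15 for fully complete /
incomplete prosody / incomplete syntax / fully incomplete) emulate the
ordering and rough magnitudes of the reference condition means; they are
conventions, not measurements. The `strong_effects` regime used for
recovery studies (0.85 / 0.50 / 0.15 / 0.02, `follow_bias` 0.9, low
dropout) was fixed a priori by a power analysis: after attenuation by
chance-level hits (~0.1–0.15), late glances (~3%), and occasional
criterion-1 failures, the implied syntax and prosody effects on the
corrected scale are ≈ 0.25 and ≈ 0.11, giving Wald z well above 4 at 20
participants so the 95/100 recovery bound holds with margin.

What the simulator does **not** emulate — smooth pursuit, saccade
kinematics, calibration drift, systematic AOI bias, autocorrelated
validity loss, linguistic comprehension, or any dependence of background
gaze on utterance content. Passing closed-loop and recovery tests
therefore shows the *pipeline* is correct and well-calibrated under its
own assumptions; it says nothing about whether real toddlers behave like
the generative model.

## Numerical conventions and degenerate inputs

Half-open intervals everywhere; a fixation ending exactly at silence onset
does not overlap the pre-silence region. Region edges belong to the
region (regions are disjoint, so no ties). Empty trials, baselines outside
[0, 1], windows longer than their conversation, subsets with < 2 subjects
or items, and invalid configs raise descriptive errors; optimizer
degeneracies are flagged, not raised. The pipeline seed fans out to named
substreams (design / cohort / shuffles) via `SeedSequence`, so reruns and
stage-wise runs are bit-reproducible.

## Problem sizes used in validation

Null calibration runs 40 participants (20 per group) × 8 conversations
with 100 shuffles per trial; effect recovery runs 100 replicate cohorts of
20 participants; detector-oracle equivalence samples 10,000 random dwell
sequences of length ≤ 12; the observation-level parameter-recovery study
runs 100 replicates at 37 subjects × 32 items. These sizes give
Monte-Carlo error comfortably below the effects being checked while
keeping the whole validation suite runnable on a laptop in a few minutes.

## Known limitations

* The published per-coefficient values of the reference analyses are not
  reproducible — the participant data were never deposited — so the suite
  validates structure, calibration, and recovery, not printed
  coefficients.
* Reported trial totals in the reference bookkeeping (1056, 1144) do not
  close arithmetically against participants × targets; trial accounting
  is reported in audits but not asserted.
* The chance baseline is always empirical (shuffled windows); no
  closed-form chance model is provided.
* With only 100 shuffles the baseline has granularity 0.01; corrected
  values inherit it.
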