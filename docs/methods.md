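# Methods

This note records the scientific and numerical choices behind
`actisleep`: what the scorers compute, what the synthetic generator does
and does not emulate, and where the design was genuinely open.

## The count-scaled scorer

The algorithm operates in local clock time on vertical-axis counts.
Stages: minute aggregation → scaling → weighted-window thresholding →
run-length event detection → flag-anchored onset/offset location.

**Scaling.**  The scale factor is the mean of strictly positive values;
after scaling the non-zero values average 1, which is what lets a single
threshold of 1 transfer across devices and sites with different count
sensitivities.  By default the mean is taken over *minute* totals (the
resolution the classifier runs at); an epoch-resolution option exists
because "non-zero epochs" is ambiguous once the epoch and classification
resolutions differ.  An all-zero recording scales by 1 — the mean of an
empty set is undefined and identity is the only neutral choice.  The
whole pipeline is invariant to multiplying a recording by any positive
constant (a tested property).

**Weights.**  The published description of the algorithm states the
window (current minute, 4 before, 2 after) but not the weight vector, so
the weights are a configurable 7-vector recorded in provenance, with the
uniform windowed mean as default.  Users holding the original weights can
supply them without touching code.

**Edges and ties.**  At the recording edges the window truncates and the
surviving weights are renormalised to the full-window total; padding with
zeros would bias edge minutes toward sleep.  The threshold comparison is
strict (< 1 = sleep), and values within one part in 10⁹ of the threshold
are snapped to it first: a weighted sum that equals the threshold in real
arithmetic (constant recording, uniform weights) must classify as wake
even when floating-point rounding leaves it an ulp below.  The backward
onset/offset search window is half-open, `[flag − 2 h, flag)`, so an
event exactly at the flag is claimed by the forward pass only.

**Resolution bookkeeping.**  Classification happens per minute (the
window definition is in minutes); validation happens per 15-s epoch (PSG
epochs are halved to match).  Each minute's label is copied to its four
constituent epochs; a trailing partial minute carries no label.  Event
times are the starting minute of the defining run: a sleep event is the
first minute of the 15-min sleep run, a wake event the last minute of
sleep before the 5-min wake run.

## Sadeh comparator

The index uses the published 1994 coefficients (7.601, −0.065, −1.08,
−0.056, −0.703) as defaults; they are parameters because the equation as
printed in the validation study is incomplete and variant coefficient
sets circulate.  "The last 6 min" for σ is read as the six minutes ending
at and including the current epoch (the standard convention), with the
sample SD (ddof 1) and σ = 0 for a single-minute window.  Counts are
capped at 300 before scoring — standard Sadeh preprocessing — and the cap
is toggleable since the study does not state whether it was applied.
Edge windows truncate rather than pad.  Epoch-by-epoch PSG comparison is
reserved for 15-s scorers; Sadeh (1-min epochs) is compared at outcome
level only, using a wake-wins rule when a 30-s PSG pair must collapse to
one minute.  Onset/offset for Sadeh-scored nights reuse the count-scaled
flag/event logic, recorded in provenance.

## Outcomes

SPT = offset − onset; WASO = wake minutes strictly between onset and
offset; TST = SPT − WASO; efficiency = 100·TST/SPT.  These identities are
enforced by the `SleepOutcomes` container itself, so no code path can
produce an inconsistent row.  WASO counts every wake minute by default,
matching the printed definition; the 5-min minimum-bout convention common
in paediatric actigraphy is available as `waso_min_bout_min=5`.  The
efficiency footnote in the source tables ("(TST − WASO)/duration") double
subtracts WASO and is not implemented; the prose definition is.  Sleep
latency is not computed: the automated scorer has no lights-out marker.
A single-subject summary reports SD 0 with an explicit small-n flag
rather than a silent missing value.

## Validation statistics

PABAK = 2·p_o − 1 with a normal-approximation CI on p_o; the identity
PABAK = 2·(accuracy/100) − 1 is enforced in the container and holds for
the subject-level mean too (PABAK is linear in accuracy).  Landis–Koch
bands are upper-inclusive ((0.60, 0.80] substantial, etc.).  A metric
with an empty denominator (e.g. specificity on a night PSG scored as all
sleep) is reported as undefined, never 0.  The published agreement table
prints CIs without naming a method, so two summaries are reported and
labelled: pooled (summed confusion cells) and subject-level mean with a
seeded percentile bootstrap over subjects (2000 resamples).  Bland–Altman
limits are mean ± 1.96·SD of device − PSG differences (sample SD).
Paired *t* is two-sided; Wilcoxon signed-rank drops zero differences and
uses the normal approximation with continuity correction.  All-zero
difference vectors return p = 1 with a zero-variance flag.  Epoch
comparison is restricted to the PSG/actigraphy overlap — no extrapolation
beyond the PSG recording.

One documented inconsistency: in the published agreement table the
wrist-Actical row (accuracy 86.0, PABAK 0.79, CI "0.65, 0.66") cannot
satisfy the PABAK identity; the implementation follows the formula and
does not emulate that row.  The wrist-ActiGraph and hip-Actical printed
PABAKs sit one printed ulp above the identity value computed from the
*rounded* accuracies (0.804 → printed 0.81; 0.734 → printed 0.74),
consistent with rounding from unrounded accuracies; the recomputed values
remain inside the printed CIs.

## Synthetic generator

The generator separates truth from observation.  Truth is a night
structure — bedtime, settling latency (lognormal), final wake (normal
clock times), and disjoint WASO bouts (Poisson count,
shifted-exponential durations placed uniformly with rejection) — and
truth outcomes come from this structure, never from re-scored data, so
recovery error is attributable to the scorer alone.  Observations are a
30-s hypnogram rendered from the structure (sleep epochs cycle
N1-N2-N3-N2-R cosmetically) and 15-s count series per site emitted
conditionally independently given the behavioural state
(zero-inflated negative binomial; a `dispersion=None` escape makes the
non-zero emission deterministic).

Three deliberate deviations from the most literal generative story:

* **Bout guard margins.**  Bouts are placed at least 20 min after sleep
  onset and 60 min before final wake (configurable).  A bout abutting
  the morning rise would silently redefine the true offset, and a bout
  inside the first minutes of sleep would invalidate the onset event
  that defines recoverability.
* **Minimum bout duration.**  `waso_bout_min_min` (default 0 = pure
  exponential) exists because a wake bout shorter than the classifier's
  detection floor is invisible to *any* 1-min count algorithm; the
  clean-recovery scenario sets it to 4 min so that truth is recoverable
  in principle.
* **Grid snapping.**  Structure times snap to the epoch grid (15 s by
  default, 60 s in the noise-free preset) so truth and scored times
  share a grid and recovery error is not dominated by sub-epoch phase.

**Emission levels.**  No raw count statistics are published for the
study cohort, so magnitudes are order-of-magnitude choices: a few
hundred counts per 15-s epoch for ambulatory wake, tens for fidgeting,
small frequent twitches in sleep.  The sleep movement floor is
structural, not cosmetic: real recordings contain many low-count epochs
that pull the non-zero mean well below waking activity, which is what
places scaled wake activity near 2 rather than hovering at the threshold.
In the noise-free preset the parameters are chosen analytically to pin
scaled wake activity inside (1.75, 2.33) — in that regime the uniform
7-min window resolves state transitions to within one minute and detects
bouts of ≥ 4 min at their exact duration, which is what makes the ±1 min
onset/offset and ±2 min WASO recovery checks meaningful tests of the
event logic rather than of emission noise.

The site asymmetry encodes the mechanism discussed for placement
effects: the trunk is motionless while a child settles (hip quiet,
settling scored as sleep → hip onset near bedtime) while the hands keep
moving (wrist active → wrist onset near true sleep onset), and hands
move more than the trunk during night wakings and sleep (wrist detects
WASO the hip misses).  The default cohort is 28 subjects, the study's
size.

What the generator does **not** emulate: autocorrelated movement bouts
within a state (emissions are conditionally independent; a bout-duration
extension hook is left in the parameter map), circadian structure,
physiologically realistic stage dynamics, device noise floors, or
non-wear.  Passing recovery tests therefore demonstrates correctness of
the scoring and validation logic under the stated generative
assumptions, not field accuracy on real children.

## Problem sizes

Defaults keep everything laptop-fast: recovery checks use 20 noise-free
nights and 50 default nights (a 16-h recording is 3 840 15-s epochs);
oracle-equivalence suites use 1000 random label sequences (≤ 500 min)
and 100 random count series; the Bland–Altman coverage check uses 10 000
simulated differences; the bootstrap uses 2000 resamples.  The full test
suite runs in well under a minute.

## Known limitations

* The original weight vector of the published count-scaled
  implementation is not recoverable from its description; results with
  the uniform default will differ from the reference implementation in
  unknown ways.
* Whether the offset search mirrors the onset search exactly
  (forward-then-backward) is a reading of "performs in a similar way";
  the mirrored behaviour is a documented decision.
* Only the vertical axis is used; tri-axial vector magnitudes, raw-g
  processing, nap detection and the interactive visual-scoring mode are
  out of scope.
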