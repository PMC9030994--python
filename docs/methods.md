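# Methods

This note records the modelling choices behind jitaikit: what the
decision engine assumes, what the synthetic-data generator emulates (and
does not), and where the design was genuinely open.

## Decision engine

**Rule table.** The thirteen rules are a partition of the decision
contexts spanned by slot × goal kind × goal progress × weather class ×
congratulation state: one option-1 rule (goal achieved, any goal kind,
evaluated at the hourly checks, at most once per day), eight option-2
rules ({steps, minutes} × {12:30, 17:30 slot} × {good, bad weather}),
and four option-3 rules ({steps, minutes} × {good, bad} at 20:30).
The partition property is enforced at load time by exhaustive
enumeration of all valid contexts, so a malformed table (e.g. two rules
firing for one context) is rejected before any day runs. Rule tables
are plain records (JSON/YAML-compatible), so degenerate tables can be
injected in tests.

**Timing.** All times are participant-local wall clock; no time-zone
arithmetic. Hourly checks run at minute :00 from 9:00 through 20:00
inclusive (12 checks); the scheduled tailored sends are at 12:30, 17:30
and 20:30. The engine stops after the 20:30 slot; nothing is evaluated
overnight.

**Goal progress.** "Met" means today's cumulative value for the goal's
kind is ≥ the target (boundary inclusive — hitting the target exactly
counts). Raising the count can never un-meet a goal within a day.

**Weather.** A window is *good* iff the maximum precipitation
probability over all 3-hour forecast blocks intersecting it is strictly
below 0.5; a block at exactly 0.5 classifies the window bad. The 12:30
and 17:30 slots look at the next 4 hours. The 20:30 slot classifies
*tomorrow's* daytime window, 12:00–16:00, because option-3 messages
speak about plans for tomorrow. This last choice was open — the
alternative (tonight's weather) fits the published message texts worse.

**Suppression and caps.** Once the goal is met, the option-2/3
predicates (which require "not yet met") stop firing, and the option-1
rule fires at most once per day, so a participant-day carries at most
one congratulation, at most three scheduled sends, and never more than
four message events. Scheduled slots always log a row; when no rule
fires (goal already met, or a data call failed) the row's status is
`suppressed` with no rule/message id, giving the metrics layer an
evaluation denominator. Hourly checks log a row only when the
congratulation fires, to keep the event log readable.

**Staleness.** The engine always uses the latest available activity
snapshot; if the snapshot's last sync precedes the decision time by
more than 4 hours the event is flagged `stale` but still evaluated —
sync lag is recorded, not acted on.

**Delivery and rating.** Each fired rule draws one message
(uniform without replacement within the pool, per participant;
exhausted pools reset), renders `[NAME]`, and succeeds as a
Bernoulli(1 − failure probability) trial. Thumbs-up/down ratings are
carried in the event schema but never feed back into rule selection.

## Goal setting and EMA calendar

Goal increments are restricted to +500/750/1000 steps or +10/20/30
active minutes over the baseline-week daily mean. A participant counts
as onboarded once both a goal and a 1–10 self-efficacy rating are
recorded; without a goal the engine emits nothing (this reproduces the
failure mode in which interrupted onboarding silences all messaging).
Goal reviews are scheduled 14 and 28 days after the intervention start;
a revised goal keeps the original baseline.

Each intervention week (boundaries at the start weekday), one weekday
and one weekend day are drawn uniformly; both carry snippet prompts at
12:30 and 17:30 and a mood questionnaire at 20:30. The well-being
questionnaire is prompted on exactly one of the two days, chosen
uniformly. This yields 16/8/4 prompts over four weeks — the calendar
denominators used for compliance. The once-weekly well-being prompt was
an open design point: prompting it on both EMA days would give a
denominator of 8, inconsistent with per-participant totals of 4; the
once-weekly reading is the one consistent with those totals.
The mood instrument's deployed item count is configurable and defaults
to 6 bipolar items on a 6-point scale (short-form convention); the
well-being scale has 7 items on a 7-point scale. Only raw item scores
are recorded — no psychometric scoring or metric conversion.

## Synthetic-data generator

The generator's job is to make every module testable end-to-end, with
moment-matchable knobs — not to microsimulate human activity.

**Steps.** Cumulative steps are sampled at 15-minute ticks (the
tracker's upload cadence). Tick increments are Poisson with rates
proportional to an hourly diurnal weight profile (waking hours
6:00–22:00; quiet mornings, late-morning and mid-afternoon peaks),
scaled so the rates sum to the participant's baseline daily mean, then
multiplied by a gamma-distributed day factor with mean 1 and
coefficient of variation `day_cv` (default 0.25). The day factor
supplies realistic day-to-day variation: without it, daily totals would
concentrate within ±√baseline (≈70 steps at a 5000-step baseline) and a
+500-step goal would sit seven standard deviations above the mean —
unreachable. The unconditional daily mean remains exactly the baseline,
which is what the moment-recovery checks assert.

**Receptivity.** Each *delivered* prompt injects extra Poisson
increments with total expectation `receptivity_effect` (default 100
steps) spread over the eight ticks following delivery. The engine
exposes a delivery hook, so within a run the boost is visible to later
goal checks the same day — the behavioural response is just-in-time,
not retrofitted. The default is a deliberately modest fraction of the
≈775 steps/day aggregate effect reported for pedometer-based
interventions in older adults.

**Active minutes.** A tick contributes 15 active minutes when its step
count reaches the cadence threshold (default 100 steps per tick).
Tracker "active minutes" are proprietary; this cadence definition is
transparent but permissive — at typical baselines many ticks qualify,
so minutes goals are often met early in the day. The threshold is a
config knob for stricter definitions.

**Snapshots.** The activity source returns the trace value 15 minutes
(one tick) before the query time, matching the stated upload cadence;
`last_sync` is the tick boundary actually seen.

**Weather.** Each 3-hour block is *wet* with probability
`rain_block_prob` (default 0.3); wet blocks draw a precipitation
probability uniformly from [0.5, 1), dry blocks from [0, 0.5). The
probability a block classifies rainy is therefore exactly
`rain_block_prob`, and a window spanning k fresh blocks is good with
probability (1 − q)^k — the closed form the weather tests check
against.

**Cohort and compliance.** Baselines are truncated normals
(steps: mean 5000, SD 2000; minutes: mean 25, SD 12 — plausible for an
older ambulatory cohort); goal choices follow configurable
probabilities over the six options (default uniform). A configurable
fraction (default 13%) is left un-onboarded. Message delivery failures
(default 6%), activity-call failures (default 1%), weather-call
failures (default 0%), EMA responses (default 45%) and survey
responses (default 97%) are independent Bernoulli draws. Wear hours are
truncated normal on [0, 24] (mean 18, SD 4). Baseline and follow-up
wear weeks are 8 days, mirroring an "8 consecutive days" deployment.
A failed data call at a scheduled slot suppresses that slot's message
(a message cannot be compiled without its tailoring inputs).

**Determinism.** All randomness descends from a single seed through
`numpy.random.SeedSequence` spawning (separate streams per participant
for traces, boosts, engine draws, EMA, wear and survey), participants
are processed in id order, and the writers are canonical — identical
config + seed reproduces byte-identical log bundles.

**What passing tests do not show.** The generator has no
autocorrelation beyond the day factor, no weather–activity coupling, no
within-person trends, habituation or receptivity heterogeneity, and its
diurnal weights are illustrative (no empirical intraday traces were
available to calibrate them). Tests passing on this generator validate
the *logic* of the engine, scheduler and metrics — not behavioural
predictions about real cohorts.

## Metrics

Delivery rate = delivered / attempted message events; option-1 share =
delivered congratulations / all delivered. Data-call success rates are
computed over scheduled-slot rows (each logs its activity and weather
call outcome). EMA compliance is the mean (and sample SD) over
participants of completed/scheduled per prompt kind, with the calendar
as denominator. Rates with empty denominators are reported as
undefined, never 0. Wear validity requires ≥4 days with ≥16 h wear, at
least one of them a Saturday/Sunday; the implementation is checked
against subset enumeration on all 2^8 eight-day patterns.
Acceptability: per-question means over respondents on the 1–5 scale;
a category score is the mean of its question means (reported /5 and as
a percentage of 5) — mean-of-means is the reading consistent with
category scores printed on a /5.00 scale; "agreement" counts responses
of 4 or 5 with per-question denominators (item-level missingness
excludes a question and flags it).

## Problem sizes

The statistical suites use sizes chosen for tight-enough binomial
standard errors at desk scale: 10,000 draws for selection uniformity
and weather-fraction checks, 2,000 simulated days for trace-mean
recovery, and a 360-participant × 28-day trial (≈10,000
participant-days) for delivery and compliance recovery, all at 3-SE
tolerances with fixed seeds.
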