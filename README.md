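# jitaikit

A testable engine for a **just-in-time adaptive intervention (JITAI)**
that promotes physical activity in older adults through a wearable
activity tracker and a companion smartphone app. The package
re-implements the intervention's decision logic as a library — tailored
message selection, goal setting, ecological momentary assessment (EMA)
scheduling — together with a synthetic-cohort simulator and a
feasibility-metrics reporter, so the whole stack can be exercised,
audited and extended without any live device, cloud or weather-service
integration.

## Who this is for

Researchers and engineers designing digital behaviour-change
interventions who want the decision rules of a deployed JITAI as
inspectable, unit-tested code: to verify tailoring logic before a field
trial, to run virtual trials under controlled assumptions, and to
compute the standard feasibility measures (delivery rates, EMA
compliance, wear-time validity, Likert acceptability) from event logs.

## The intervention model

A participant chooses a **baseline-relative daily goal**: either
*steps* (baseline + 500, 750 or 1000) or *active minutes*
(baseline + 10, 20 or 30), where the baseline is the mean over a
preceding wear week. Messages are tailored on four variables: real-time
goal progress, goal kind, time of day, and weather ("good" iff every
3-hour forecast block touching the relevant window has a precipitation
probability strictly below 50%).

Thirteen decision rules partition these contexts into three
intervention options:

| option | rules | fires when | content |
|---|---|---|---|
| 1 | 1 | goal met, checked hourly 9:00–20:00, once per day | congratulation |
| 2 | 8 | goal not met at 12:30 or 17:30 × {steps, minutes} × {good, bad} | activity suggestion |
| 3 | 4 | goal not met at 20:30 × {steps, minutes} × {good, bad weather *tomorrow*} | next-day planning prompt |

Each rule owns a pool of 10–14 message templates; the packaged bank
holds 136 unique messages, of which any single participant can reach at
most 75 (the shared congratulation pool plus their goal kind's six
pools). Within a pool, selection is uniform without replacement,
restarting once the pool is exhausted.

The EMA calendar prompts voice *snippets* at 12:30 and 17:30 plus a
mood questionnaire at 20:30 on two random days per week (one weekday,
one weekend day), and a well-being questionnaire on one of those two
days — 16 snippet, 8 mood and 4 well-being prompts over the 4-week
intervention, with goal reviews after weeks 2 and 4.

## Worked example

Run one simulated day for a fixture participant (baseline 4200 steps,
+750 goal) who never reaches the 4950-step target:

```
$ jitaikit run-day --seed 1
goal: steps target 4950 on 2020-09-07
12:30  midday  delivered  rule 2, smg-09
         ↳ You've not reached your step goal for today yet, but there's still time! ...
17:30  evening delivered  rule 4, seg-07
         ↳ You've not reached your step goal for today yet, but there's still time! ...
20:30  night   delivered  rule 10, sng-05
         ↳ You didn't quite reach your step goal today - tomorrow is a new chance. ...
```

Exactly three tailored sends fire (the scheduled slots), none of the
twelve hourly congratulation checks does, and the rules chosen (2, 4,
10) are the steps/good-weather rules for each slot.

Run a full synthetic trial — 30 participants, 8-day baseline week,
4-week intervention, 8-day follow-up — and report feasibility:

```
$ jitaikit simulate --out-dir demo --seed 1
$ jitaikit report --logs demo
Feasibility report
==================
messages attempted        1621
messages delivered        1536 (94.8%)
option-1 share            19.2%
activity-call success     98.7%
weather-call success      100.0%
onboarding rate           83.3%
EMA mood       compliance mean 0.45 (SD 0.17) of 8 scheduled
EMA snippet    compliance mean 0.45 (SD 0.12) of 16 scheduled
EMA wellbeing  compliance mean 0.49 (SD 0.25) of 4 scheduled
wear valid (baseline    ) 28/30 participants
goal-achievement days     mean 11.1 per participant

Acceptability (1-5 scale)
  app          3.75/5.00 (75%)
  research     3.80/5.00 (76%)
  technology   3.85/5.00 (77%)
```

The delivery rate recovers the configured 6% failure probability; the
EMA compliance means recover the configured 45% response probability
against the 16/8/4 calendar denominators; onboarding rate reflects the
configured 13% onboarding-failure fraction (participants whose
interrupted onboarding leaves no goal receive no messages at all).
Category acceptability scores are means of per-question means on the
1–5 agreement scale, also expressed as a percentage of 5.

The same computations are available as a library:

```python
import numpy as np
from jitaikit import SimulationConfig, simulate_trial, compute_feasibility

logs = simulate_trial(SimulationConfig(n_participants=30, seed=1))
report = compute_feasibility(logs)
print(report.message_delivery_rate)   # 0.948...
```

## Layout

- `src/jitaikit/message_bank.py` — bank loading/validation, uniform
  no-repeat selection, `[NAME]` rendering, reachability counts
- `src/jitaikit/decision_engine.py` — the 13-rule table, weather
  classification, goal checks, and the daily decision loop
- `src/jitaikit/scheduling.py` — onboarding/goal state, biweekly
  review, activity-reminder planning, EMA calendar
- `src/jitaikit/simulate.py` — synthetic cohort, intraday traces,
  weather, delivery/compliance behaviour, the end-to-end trial
- `src/jitaikit/metrics.py` — feasibility and acceptability measures
- `src/jitaikit/io.py`, `src/jitaikit/cli.py` — log schemas, CSV/JSON
  round-trips, run manifests, command-line entry points

See `docs/methods.md` for the modelling assumptions, defaults and known
limitations.
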