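# Methods

This note defines the simulation model implemented by `edsim`, documents
every parameter with units and defaults, explains how the synthetic fixture
was constructed, and lists numerical choices and known limitations.

## 1. Model

### 1.1 Process graph

The ED layout is a directed graph of **activities** (nodes) and **arcs**
(edges), serialized as GraphML.

Node keys: `name`, `operators` (team size), `role` (comma-separated list,
one worker per listed role; a single role with `operators > 1` means that
many workers of that role), `dur_mean_s` / `dur_sd_s` (service-duration
normal parameters, seconds), `entry`, `exit`, and an optional `esi` key on
entry nodes listing the urgency levels admitted there (e.g. the Shock-Room
admits only ESI 1). Edge keys: `walk_s` (patient walking time, seconds),
`weight` (relative routing probability, default 1), optional `esi` filter.

`process_graph.validate` checks structural integrity: staffed teams, at
least one entry and exit, reachability of every node from an entry and of an
exit from every node, and — per admitted ESI level — that routing never dead
ends. `load_graphml` refuses files with missing keys (`SchemaError`) or
failing validation (`GraphValidationError`).

### 1.2 Arrivals

The number of arrivals on day *d* is Poisson with mean
`7 · daily_mean · weekday_weight(d)`. Defaults: `daily_mean = 125`
patients/day and weekday weights (Mon…Sun) 0.169, 0.150, 0.144, 0.146,
0.153, 0.124, 0.114 (they sum to 1, so the weekly total has mean
`7 · daily_mean`). Within a day, arrival times are drawn either uniformly or
from a 24-bin hourly profile; the fixture uses a rush-hour profile peaking
late morning (see §3). Each patient gets an ESI level from a categorical
mix and enters at the most specific entry admitting that level.

### 1.3 Time and the tick loop

Time advances in fixed ticks (default 60 s; any divisor of 86,400 works).
Within each tick, in order:

1. inject patients whose arrival time has come (arrival times are snapped
   up to the tick lattice);
2. for every activity with a free team and a non-empty queue, select a
   patient (policy below) and start service;
3. advance walking patients; those reaching their destination join its
   queue (or are discharged at an exit);
4. complete services whose end time has been reached; the patient routes
   onward along an admitting arc drawn by `weight`;
5. run abandonment trials for eligible waiting patients;
6. bookkeeping, including an internal conservation assertion: injected
   patients = walking + queued + in service + discharged + abandoned, every
   tick.

Because team seizing (step 2) precedes walker arrivals (step 3), each walked
hop adds at most one tick of latency before the next service can begin; all
timestamps lie on the tick lattice.

Service duration is a truncated-normal draw (strictly positive, by
rejection) divided by the mean skill of the serving team, then rounded up to
a whole number of ticks. A patient's `t_first_doctor` is set when they first
start service at a doctor-staffed activity. Worker busy time is accrued when
the team is seized, capped at the simulation end — arithmetically identical
to per-tick accrual since teams always run services to completion.

### 1.4 Selection policy

`PolicyParams` holds `priority_criteria` (integer percentage, 0–100) and a
per-ESI waiting-time threshold (seconds). Waiting time is measured from
arrival to the ED. Selection at a free team:

- **Overdue gateway.** Patients whose wait strictly exceeds their threshold
  are overdue; ESI 1 is always overdue. If any patient in the queue is
  overdue, the overdue patient with the lowest ESI (ties: largest excess,
  then lowest id) is chosen.
- **Mixed criterion.** Otherwise a uniform draw against
  `priority_criteria`/100 selects either urgency-first ordering
  (lowest ESI, ties by longest wait) or FIFO (longest wait, ties by ESI).

So `priority_criteria = 100` is urgency-first and `0` is FIFO, both still
subject to the overdue gateway.

### 1.5 Abandonment

Waiting patients who have not yet seen a doctor and whose ESI is in
`abandon_levels` (default: the two least urgent levels) leave with per-tick
probability `1 / (1 + exp(−(a0 + a1·wait_hours + a2·queue_len)))`.
`a0 = −inf` disables abandonment. Fixture defaults: `a0 = −8.0`,
`a1 = 0.5` per hour waited, `a2 = 0.03` per queued patient — a deliberately
small hazard (≈0.1–0.2 % of patients under realistic load).

### 1.6 KPIs and the Quality Score

- **DTDT** (door-to-doctor time) and **LoS** (length of stay), reported in
  minutes by ESI level with mean, sample SD and n; warm-up patients are
  excluded, LoS counts discharged patients only.
- **Utilization** per role: busy seconds / scheduled seconds.
- **Quality Score**: for each level 2…L, the squared count of patients whose
  DTDT strictly exceeded the level's threshold, summed over levels.
  Abandoned patients always count as exceedances. Patients still in the
  system who have not seen a doctor count only if their elapsed wait already
  exceeds the threshold. ESI 1 is excluded (it is handled by resuscitation
  pathways, not queue policy). Unless told otherwise, `quality_score` uses
  the thresholds of the policy that produced the run — the score audits the
  same promise the overdue gateway tries to keep. A `two_group` mode instead
  squares the totals of the urgent half ({2,3}) and the less-critical half
  ({4,5}).

Consequence worth noting: with infinite thresholds QS is zero only in the
absence of abandonment, because abandoned patients count unconditionally.

### 1.7 Optimization

The decision space is 5-dimensional, on integer grids:

| gene | range | step |
|---|---|---|
| `priority_criteria` | 0 – 100 | 5 |
| `threshold_esi2` (s) | 900 – 3,600 | 60 |
| `threshold_esi3` (s) | 1,800 – 5,400 | 60 |
| `threshold_esi4` (s) | 3,600 – 9,600 | 60 |
| `threshold_esi5` (s) | 7,200 – 14,400 | 60 |

Fitness is the mean QS over *R* replicates using **common random numbers**:
replicate *r* uses seed `SeedSequence([seed, r])` for every candidate, so
candidates differ only through policy, not luck. `sweep` evaluates a full
grid; `ga_run` is a bespoke genetic algorithm — tournament selection
(size 2), single-point crossover (rate 0.7), per-gene uniform-resample
mutation (rate 0.3), elitism 1, memoized fitness — defaults population 50,
30 generations. Elites are copied unchanged, so the best-so-far history is
monotone.

## 2. Parameters at a glance

| parameter | default | units |
|---|---|---|
| tick | 60 | s |
| horizon / warm-up | 28 / 1 | days |
| daily mean arrivals | 125 | patients/day |
| staffing | 4 doctors, 7 ED nurses, 2 triage nurses, 2 social workers | — |
| ESI mix (5-level fixture) | 0.02 / 0.08 / 0.20 / 0.45 / 0.25 | probability |
| thresholds (fixture) | 2,250 / 3,600 / 6,600 / 10,800 (range midpoints) | s |
| abandonment | a0 −8.0, a1 0.5 /h, a2 0.03 /patient | logistic |
| worker skill | 1.0 | divisor of service time |

## 3. The synthetic fixture

No real patient-level hospital data ships with this package; the fixture is
a synthetic ED chosen to be structurally realistic and fully reproducible:

- **Pathway**: Registration → Triage → Visit → {Discharge 45 %,
  Blood-analysis 25 %, Radiology 12 %, Imaging 8 %, Consultancy 10 %} →
  Discharge, plus a Shock-Room entry admitting only ESI 1 directly to a
  doctor+nurse team. Visit requires a doctor and an ED nurse together.
- **ESI mix** is low-urgency-dominated (70 % ESI 4–5), matching published
  triage distributions for walk-in-heavy EDs where minor codes dominate.
- **Hourly profile** peaks between 09:00 and 13:00 and bottoms out at night,
  the canonical ED arrival curve.
- **Load presets** scale service durations: `light` ×0.6, `realistic` ×1.0,
  `stressed` ×1.4. The stressed preset is calibrated so that rush-hour
  queues reliably form while the system still clears overnight — the regime
  in which the selection policy actually matters. Under much heavier load
  the overdue gateway dominates every policy (all become earliest-deadline
  ordering) and the QS response flattens; under light load no policy ever
  binds. In the stressed regime the QS-vs-`priority_criteria` curve is
  U-shaped with an interior optimum.

## 4. Numerical and reproducibility choices

- All randomness flows from one integer seed via `numpy.random.SeedSequence`
  spawning: one stream for arrivals (NumPy `Generator`), one for engine
  draws (Python `random.Random`). Same seed ⇒ byte-identical event logs.
- Truncated-normal sampling uses rejection (exact, no clipping bias); the
  engine test checks the sample mean against the analytic truncated mean.
- Service durations round *up* to the tick, so capacity is never
  overstated.
- Replicate seeds derive as `SeedSequence([seed, r])`, giving common random
  numbers across optimizer candidates and independence across replicates.
- Problem sizes used in the test suite and in `scripts/acceptance.py`
  (7-day sweep horizon with 10 replicates, 50 one-day random configurations,
  1,001 calibration days, 20 surrogate objectives, four-week KPI runs) are
  this package's own choices, sized for statistical stability of the
  properties being checked.

## 5. Limitations

- Workers do not walk between activities; they serve in place. Patient
  walking uses arc durations; worker movement is not modeled.
- No beds, boarding, lab turnaround queues, or diversion: resource
  contention is team availability only.
- Service times are independent truncated normals; no patient-complexity
  correlation across a patient's successive activities.
- One-tick granularity (default 60 s) bounds timestamp accuracy, and each
  walked hop can add up to one tick of latency.
- The fixture is synthetic; absolute KPI levels (utilizations, LoS) describe
  the fixture, not any particular hospital. The qualitative findings — the
  U-shape and the optimizer behavior — are the reproducible claims.
- Abandonment applies only before first doctor contact and only to the two
  least urgent levels; leaving against medical advice mid-pathway is not
  modeled.
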