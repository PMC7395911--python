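# edsim — agent-based emergency-department simulation and policy optimization

`edsim` is a discrete-time (tick-based) agent simulation of patient flow
through a hospital emergency department (ED), together with tools for
evaluating and optimizing the department's *patient-selection policy*.

## The science in brief

Patients arrive at the ED following a non-homogeneous process (Poisson daily
counts modulated by weekday weights and an intraday rush-hour profile), are
triaged into urgency levels (ESI 1 = most urgent … ESI 5 = least urgent), and
move through a care pathway — registration, triage, medical visit, optional
exams, discharge — described by a directed **process graph** (GraphML).
Each activity needs a team of staffed workers (doctors, nurses, …) with a
truncated-normal service duration scaled by worker skill.

When a team becomes free, the next patient is chosen by a two-stage policy:

1. **Check-excess-time gateway.** Any patient whose waiting time exceeds the
   per-ESI threshold is *overdue* and is served first (most urgent overdue
   patient first). ESI 1 is always overdue.
2. **Priority-criteria mix.** Otherwise, a coin with probability
   `priority_criteria`/100 decides between *urgency-first* ordering and
   *longest-wait-first* (FIFO) ordering.

Unseen low-urgency patients may **abandon** the queue (a logistic per-tick
hazard in waiting time and queue length).

Performance of a policy is summarized by the **Quality Score (QS)**: for each
ESI level 2…L, count the patients whose door-to-doctor time exceeded the
level's threshold (abandoned patients always count), square the count, and
sum. Lower is better; the square makes widespread threshold violations at any
single level disproportionately costly.

The central empirical finding reproduced by this package: under a stressed
but realistic load, **QS is U-shaped in `priority_criteria`** — pure
urgency-first ordering starves the numerous low-urgency patients past their
thresholds, pure FIFO lets tight ESI-2/3 thresholds expire, and a mixed
policy beats both extremes. The `optimize` module finds good policies over
the 5-dimensional space (priority criteria plus four thresholds) by
exhaustive sweep or by a genetic algorithm (tournament selection,
single-point crossover, per-gene mutation, elitism) with common random
numbers across candidates.

## Worked example

Generate the bundled synthetic ED (graph + config), then simulate one week:

```bash
$ edsim fixture --out demo --scale 1.0
wrote demo/fixture.graphml and demo/config.yaml

# edit demo/config.yaml: set sim.horizon_days: 7

$ edsim simulate --config demo/config.yaml --out demo/run --seed 42
INFO config demo/config.yaml hash=935546f6a43a
INFO seed=42 warm-up=[0, 86400s) horizon=7d; arrivals=1030 discharged=1026 abandoned=1 in-system=3
KPI summary (non-warm-up patients)
  ESI 1: DTDT 0.6 min (sd 2.0, n=12); LoS 46.5 min (sd 9.9, n=12)
  ESI 2: DTDT 15.0 min (sd 3.4, n=71); LoS 38.3 min (sd 9.9, n=70)
  ESI 3: DTDT 15.6 min (sd 4.3, n=168); LoS 41.4 min (sd 12.2, n=168)
  ESI 4: DTDT 16.4 min (sd 5.9, n=391); LoS 42.2 min (sd 12.2, n=391)
  ESI 5: DTDT 16.5 min (sd 5.7, n=218); LoS 41.2 min (sd 11.6, n=217)
  utilization[doctor]: 39.0%
  utilization[ed_nurse]: 27.6%
  utilization[social_worker]: 19.7%
  utilization[triage_nurse]: 24.0%
  abandoned: 1 (0.12%)
  quality score: 1
  dispositions: 858 discharged, 1 abandoned, 3 in system of 862 arrivals
```

The output above is the actual output of those commands. `demo/run/` then
contains `events.csv` (one row per patient: timestamps, final state, path),
`workers.csv` (busy time per worker) and `kpi.csv` (the tidy KPI table).
DTDT is door-to-doctor time; LoS is length of stay. The same run is available
from Python:

```python
from dataclasses import replace
from edsim import engine, fixtures, kpi

spec = fixtures.FixtureSpec(load="realistic")
graph = fixtures.build_fixture_graph(spec)
arrivals, staffing, policy, sim = fixtures.build_fixture_config(spec)
result = engine.run(graph, arrivals, staffing, policy,
                    replace(sim, horizon_days=7, seed=42))
print(kpi.build_report(result).summary())
```

Policy optimization from the command line (`sweep` scans
`priority_criteria` over 0…100; `ga` searches the full 5-D space):

```bash
edsim sweep --config demo/config.yaml --out demo/sweep --seed 1
edsim ga    --config demo/config.yaml --out demo/ga    --seed 1
```

Exit codes: 0 success, 2 configuration/validation error, 3 runtime error.

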