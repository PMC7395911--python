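"""Tick-based simulation core.

The simulation starts from an empty department at midnight on a Monday and
advances in fixed ticks (default 60 s).  Within one tick, in order:

1. new arrivals are injected and walk (instantaneously) to their entry queue;
2. at every activity with free capacity, teams are seized and the policy
   selects the next patient (service begins this tick);
3. walking patients progress along their arc; on arrival they join the
   destination queue, or are discharged if the destination is an exit;
4. running services are checked for completion; completed teams are freed;
5. completed patients are routed to their next activity and start walking;
6. waiting patients of the least urgent levels may abandon;
7. worker busy time is accumulated.

Service durations are truncated-normal draws (strictly positive), scaled by
the mean skill of the seized team and rounded up to a whole tick.  The first
day is a warm-up: its patients occupy resources but are flagged so that KPI
computations exclude them.  A run is fully determined by (configuration,
seed); identical seeds give identical event logs.
"""

from __future__ import annotations

import csv
import math
import random
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .population import (
    SECONDS_PER_DAY,
    ArrivalConfig,
    Patient,
    Worker,
    generate_day_arrivals,
    roster_workers,
)
from .policy import PolicyParams, QueueEntry, select_next_patient, should_abandon, route_next
from .process_graph import Activity, ProcessGraph, validate

__all__ = [
    "SimConfig",
    "RunResult",
    "EngineError",
    "service_duration",
    "draw_service_seconds",
    "TickSimulation",
    "run",
]


class EngineError(RuntimeError):
    """An engine invariant was violated or a team was mis-composed."""


@dataclass
class SimConfig:
    """Simulation horizon and resolution."""

    horizon_days: int = 28
    warmup_days: int = 1
    tick_seconds: int = 60
    seed: int = 0
    replicate_count: int = 10
    record_selections: bool = False
    record_queue_lengths: bool = False

    def __post_init__(self) -> None:
        if self.horizon_days < 1:
            raise ValueError("horizon_days must be >= 1")
        if self.warmup_days < 0:
            raise ValueError("warmup_days must be >= 0")
        if self.tick_seconds <= 0 or SECONDS_PER_DAY % self.tick_seconds != 0:
            raise ValueError("tick_seconds must be positive and divide 86,400")

    @property
    def total_days(self) -> int:
        return self.warmup_days + self.horizon_days

    @property
    def sim_end(self) -> int:
        return self.total_days * SECONDS_PER_DAY

    @property
    def warmup_seconds(self) -> int:
        return self.warmup_days * SECONDS_PER_DAY


@dataclass
class SelectionRecord:
    """Audit record of one patient-selection event."""

    time: float
    activity: str
    chosen_id: int
    #: queue snapshot at the instant of selection: (patient id, esi, waiting_since)
    queue: tuple[tuple[int, int, float], ...]


@dataclass
class RunResult:
    """Event log and accumulators of a single simulation run."""

    patients: list[Patient]
    workers: list[Worker]
    sim_end: float
    warmup_seconds: float
    seed: int
    config: dict = field(default_factory=dict)
    selections: list[SelectionRecord] | None = None
    queue_lengths: pd.DataFrame | None = None

    @property
    def scheduled_seconds(self) -> float:
        """Per-worker scheduled time (24/7 staffing: the whole simulated span)."""
        return self.sim_end

    def kpi_patients(self) -> list[Patient]:
        """Patients counted in KPIs (arrived after the warm-up period)."""
        return [p for p in self.patients if not p.warmup]

    def totals(self) -> dict[str, int]:
        c = Counter(p.state for p in self.patients)
        return {
            "arrivals": len(self.patients),
            "discharged": c.get("discharged", 0),
            "abandoned": c.get("abandoned", 0),
            "in_system": len(self.patients)
            - c.get("discharged", 0)
            - c.get("abandoned", 0),
        }

    def patients_df(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": p.id,
                "esi": p.esi,
                "t_arrival": p.t_arrival,
                "t_first_doctor": p.t_first_doctor,
                "t_discharge": p.t_discharge,
                "final_state": p.state,
                "warmup": p.warmup,
                "path": ";".join(p.path),
            }
            for p in self.patients
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "patient_id",
                "esi",
                "t_arrival",
                "t_first_doctor",
                "t_discharge",
                "final_state",
                "warmup",
                "path",
            ],
        )

    def workers_df(self) -> pd.DataFrame:
        rows = [
            {
                "worker_id": w.id,
                "role": w.role,
                "skill": w.skill,
                "busy_seconds": w.busy_seconds,
                "scheduled_seconds": self.scheduled_seconds,
            }
            for w in self.workers
        ]
        return pd.DataFrame(
            rows,
            columns=["worker_id", "role", "skill", "busy_seconds", "scheduled_seconds"],
        )

    def write_event_csv(self, path) -> None:
        """Fixed-column event log; byte-identical for identical runs."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                [
                    "patient_id",
                    "esi",
                    "t_arrival",
                    "t_first_doctor",
                    "t_discharge",
                    "final_state",
                    "path",
                ]
            )
            for p in self.patients:
                w.writerow(
                    [
                        p.id,
                        p.esi,
                        _fmt_t(p.t_arrival),
                        _fmt_t(p.t_first_doctor),
                        _fmt_t(p.t_discharge),
                        p.state,
                        ";".join(p.path),
                    ]
                )

    def write_worker_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["worker_id", "role", "skill", "busy_seconds", "scheduled_seconds"])
            for wk in self.workers:
                w.writerow(
                    [wk.id, wk.role, wk.skill, _fmt_t(wk.busy_seconds), _fmt_t(self.scheduled_seconds)]
                )


def _fmt_t(t: float | None) -> str:
    if t is None:
        return ""
    return str(int(t)) if float(t).is_integer() else repr(float(t))


def draw_service_seconds(mean: float, sd: float, rng: random.Random) -> float:
    """Normal(mean, sd) truncated strictly above 0, by rejection."""
    if sd == 0:
        return float(mean)
    while True:
        d = rng.gauss(mean, sd)
        if d > 0:
            return d


def service_duration(
    activity: Activity,
    team: list[Worker],
    rng: random.Random,
    tick_seconds: int = 60,
) -> int:
    """Sampled service duration in seconds for a seized team.

    The truncated-normal draw is divided by the team's mean skill and rounded
    up to a whole tick.  The team must match the activity's role requirements.
    """
    if len(team) != activity.operators_required:
        raise EngineError(
            f"activity {activity.name!r} needs {activity.operators_required}"
            f" operators, got {len(team)}"
        )
    if Counter(w.role for w in team) != Counter(activity.roles):
        raise EngineError(
            f"activity {activity.name!r} needs roles {sorted(activity.roles)},"
            f" got {sorted(w.role for w in team)}"
        )
    d = draw_service_seconds(activity.service_mean, activity.service_sd, rng)
    skill = sum(w.skill for w in team) / len(team)
    d /= skill
    ticks = max(1, math.ceil(round(d / tick_seconds, 9)))
    return ticks * tick_seconds


class TickSimulation:
    """Mutable simulation state advanced one tick at a time."""

    def __init__(
        self,
        graph: ProcessGraph,
        arrivals: list[Patient],
        workers: list[Worker],
        policy_params: PolicyParams,
        sim_cfg: SimConfig,
        rng: random.Random,
    ) -> None:
        violations = validate(graph)
        if violations:
            raise EngineError("invalid process graph: " + "; ".join(violations))
        self.graph = graph
        self.params = policy_params
        self.cfg = sim_cfg
        self.rng = rng
        self.clock = 0
        tick = sim_cfg.tick_seconds
        # snap arrival instants up to the tick lattice; drop post-horizon stragglers
        self.pending = []
        for p in arrivals:
            snapped = math.ceil(p.t_arrival / tick) * tick
            if snapped < sim_cfg.sim_end:
                p.t_arrival = float(snapped)
                p.warmup = p.t_arrival < sim_cfg.warmup_seconds
                self.pending.append(p)
        self.pending.sort(key=lambda p: (p.t_arrival, p.id))
        self.next_arrival = 0
        self.injected: list[Patient] = []
        self.workers = workers
        self.free: dict[str, list[Worker]] = {}
        for w in workers:
            self.free.setdefault(w.role, []).append(w)
        self.queues: dict[str, list[QueueEntry]] = {
            name: [] for name in graph.activities
        }
        self.walking: list[list] = []  # [patient, remaining_s, destination]
        self.services: list[list] = []  # [end_time, patient, team, activity_name]
        self.n_discharged = 0
        self.n_abandoned = 0
        self._out_arcs = {name: graph.out_arcs(name) for name in graph.activities}
        self._need = {
            name: Counter(act.roles) for name, act in graph.activities.items()
        }
        self._order = sorted(graph.activities)
        self.selections: list[SelectionRecord] = []
        self._queue_series: list[tuple] = []

    # -- helpers -----------------------------------------------------------

    def _enter(self, patient: Patient, activity_name: str) -> None:
        """Patient arrives at an activity: queue up, or discharge at an exit."""
        patient.current_location = activity_name
        patient.path.append(activity_name)
        act = self.graph.activities[activity_name]
        if act.is_exit:
            patient.state = "discharged"
            patient.t_discharge = float(self.clock)
            patient.next_task = None
            self.n_discharged += 1
            return
        patient.state = "waiting"
        self.queues[activity_name].append(
            QueueEntry(patient=patient, waiting_since=patient.t_arrival, activity=activity_name)
        )

    def _start_walk(self, patient: Patient, dest: str, walk_seconds: float) -> None:
        tick = self.cfg.tick_seconds
        walk = math.ceil(round(walk_seconds / tick, 9)) * tick
        if walk <= 0:
            self._enter(patient, dest)
        else:
            patient.state = "walking"
            patient.next_task = dest
            self.walking.append([patient, walk, dest])

    def _team_available(self, name: str) -> bool:
        need = self._need[name]
        return all(len(self.free.get(role, [])) >= n for role, n in need.items())

    def _seize_team(self, name: str) -> list[Worker]:
        team = []
        for role, n in self._need[name].items():
            pool = self.free[role]
            for _ in range(n):
                team.append(pool.pop())
        return team

    # -- tick --------------------------------------------------------------

    def step(self) -> None:
        """Advance the simulation by one tick."""
        now = self.clock
        tick = self.cfg.tick_seconds
        record_sel = self.cfg.record_selections

        # 1. inject arrivals
        while (
            self.next_arrival < len(self.pending)
            and self.pending[self.next_arrival].t_arrival <= now
        ):
            p = self.pending[self.next_arrival]
            self.next_arrival += 1
            self.injected.append(p)
            entry = route_next(p, self.graph, self.rng)  # entry for this ESI
            self._enter(p, entry)

        # 2. seize teams and select patients
        for name in self._order:
            queue = self.queues[name]
            if not queue:
                continue
            while queue and self._team_available(name):
                chosen = select_next_patient(queue, self.params, now, self.rng)
                if chosen is None:
                    break
                if record_sel:
                    self.selections.append(
                        SelectionRecord(
                            time=float(now),
                            activity=name,
                            chosen_id=chosen.patient.id,
                            queue=tuple(
                                (e.patient.id, e.patient.esi, e.waiting_since)
                                for e in queue
                            ),
                        )
                    )
                queue.remove(chosen)
                team = self._seize_team(name)
                act = self.graph.activities[name]
                duration = service_duration(act, team, self.rng, tick)
                end = now + duration
                patient = chosen.patient
                patient.state = "in_service"
                patient.next_task = None
                if patient.t_first_doctor is None and "doctor" in act.roles:
                    patient.t_first_doctor = float(now)
                for w in team:
                    w.state = "busy"
                    w.assigned_patient = patient.id
                    # services always run to completion; cap at the horizon
                    w.busy_seconds += min(end, self.cfg.sim_end) - now
                self.services.append([end, patient, team, name])

        # 3. progress walkers
        if self.walking:
            still = []
            for item in self.walking:
                item[1] -= tick
                if item[1] <= 0:
                    self._enter(item[0], item[2])
                else:
                    still.append(item)
            self.walking = still

        # 4-5. complete services and route patients onward
        if self.services:
            running = []
            for item in self.services:
                end, patient, team, name = item
                if end <= now:
                    for w in team:
                        w.state = "seeking"
                        w.assigned_patient = None
                        self.free[w.role].append(w)
                    nxt = route_next(patient, self.graph, self.rng, now=now)
                    if nxt is not None:
                        arc = self._arc(name, nxt, patient.esi)
                        self._start_walk(patient, nxt, arc.walk_seconds)
                else:
                    running.append(item)
            self.services = running

        # 6. abandonment trials
        if self.params.abandon_a0 != -math.inf:
            for name in self._order:
                queue = self.queues[name]
                if not queue:
                    continue
                qlen = len(queue)
                keep = []
                for e in queue:
                    if e.patient.esi in self.params.abandon_levels and should_abandon(
                        e, qlen, now, self.params, self.rng
                    ):
                        e.patient.state = "abandoned"
                        e.patient.next_task = None
                        self.n_abandoned += 1
                    else:
                        keep.append(e)
                if len(keep) != qlen:
                    self.queues[name] = keep

        # 7. bookkeeping and invariants (busy time accrued at seize, step 2)
        if self.cfg.record_queue_lengths:
            self._queue_series.append(
                (now, *(len(self.queues[n]) for n in self._order))
            )
        in_system = (
            len(self.walking)
            + sum(len(q) for q in self.queues.values())
            + len(self.services)
        )
        if len(self.injected) != in_system + self.n_discharged + self.n_abandoned:
            raise EngineError(
                f"conservation violated at t={now}: {len(self.injected)} arrivals"
                f" != {in_system} in system + {self.n_discharged} discharged"
                f" + {self.n_abandoned} abandoned"
            )
        self.clock = now + tick

    def _arc(self, src: str, dst: str, esi: int):
        for a in self._out_arcs[src]:
            if a.dst == dst and a.admits(esi):
                return a
        raise EngineError(f"no arc {src!r}->{dst!r} admitting ESI {esi}")

    def run_to_end(self) -> None:
        while self.clock < self.cfg.sim_end:
            self.step()

    def result(self, seed: int, config_echo: dict | None = None) -> RunResult:
        queue_df = None
        if self.cfg.record_queue_lengths:
            queue_df = pd.DataFrame(
                self._queue_series, columns=["time", *self._order]
            )
        return RunResult(
            patients=self.injected,
            workers=self.workers,
            sim_end=float(self.cfg.sim_end),
            warmup_seconds=float(self.cfg.warmup_seconds),
            seed=seed,
            config=config_echo or {},
            selections=self.selections if self.cfg.record_selections else None,
            queue_lengths=queue_df,
        )


def run(
    graph: ProcessGraph,
    arrival_cfg: ArrivalConfig,
    staffing: dict[str, int],
    policy_params: PolicyParams,
    sim_cfg: SimConfig,
    skills: dict[str, float] | None = None,
) -> RunResult:
    """Simulate ``warmup_days + horizon_days`` from Monday 00:00.

    Warm-up patients are simulated but flagged for exclusion from KPIs.
    The result is a pure function of the arguments and ``sim_cfg.seed``.
    """
    seed = int(sim_cfg.seed)
    ss = np.random.SeedSequence(seed)
    arrival_ss, engine_ss = ss.spawn(2)
    arrival_rng = np.random.default_rng(arrival_ss)
    engine_rng = random.Random(int(engine_ss.generate_state(1)[0]))

    arrivals: list[Patient] = []
    next_id = 0
    for day in range(sim_cfg.total_days):
        day_patients = generate_day_arrivals(
            day, arrival_cfg, arrival_rng, start_id=next_id, graph=graph
        )
        next_id += len(day_patients)
        arrivals.extend(day_patients)

    workers = roster_workers(staffing, skills)
    sim = TickSimulation(graph, arrivals, workers, policy_params, sim_cfg, engine_rng)
    sim.run_to_end()
    echo = {
        "horizon_days": sim_cfg.horizon_days,
        "warmup_days": sim_cfg.warmup_days,
        "tick_seconds": sim_cfg.tick_seconds,
        "daily_mean": arrival_cfg.daily_mean,
        "staffing": dict(staffing),
        "priority_criteria": policy_params.priority_criteria,
        "thresholds": dict(policy_params.thresholds),
    }
    return sim.result(seed=seed, config_echo=echo)
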