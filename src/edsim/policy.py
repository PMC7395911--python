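"""Patient-selection policy, routing, and abandonment.

A free team chooses the next patient from its activity's queue by combining
two criteria: clinical urgency (the ESI level, 1 = most urgent) and time
already spent in the department.  The *priority-criteria* parameter is the
percentage probability that urgency wins the coin flip; otherwise the
longest-waiting patient is taken.  Independently, a *check-excess-time*
gateway promotes any patient whose wait has exceeded the maximum tolerated
for its urgency level: overdue patients are always served first, the most
urgent and then the most overdue among them.  ESI-1 patients are never
queued behind anyone.

Patients of the least urgent levels may abandon the department before seeing
a doctor.  Abandonment is modelled as a per-tick Bernoulli event with a
logistic hazard in the hours waited and the current queue length:

    p = 1 / (1 + exp(-(a0 + a1 * wait_hours + a2 * queue_len)))

Setting ``a0 = -inf`` disables abandonment.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from .population import ConfigError, Patient
from .process_graph import GraphValidationError, ProcessGraph

__all__ = [
    "DEFAULT_THRESHOLD_BOUNDS",
    "PolicyParams",
    "QueueEntry",
    "overdue_patients",
    "select_next_patient",
    "should_abandon",
    "route_next",
]

#: Waiting-threshold search bounds per ESI level, in seconds.
DEFAULT_THRESHOLD_BOUNDS = {
    2: (900, 3_600),
    3: (1_800, 5_400),
    4: (3_600, 9_600),
    5: (7_200, 14_400),
}


@dataclass
class PolicyParams:
    """Tunable parameters of the patient-selection policy."""

    priority_criteria: int = 50  # percent chance urgency wins, 0..100
    #: Max tolerated wait (s) before promotion, per ESI level 2..L; ESI 1 exempt.
    thresholds: dict[int, float] = field(
        default_factory=lambda: {
            l: (lo + hi) / 2 for l, (lo, hi) in DEFAULT_THRESHOLD_BOUNDS.items()
        }
    )
    abandon_a0: float = -math.inf  # -inf disables abandonment
    abandon_a1: float = 0.0  # per waiting hour
    abandon_a2: float = 0.0  # per patient in queue
    abandon_levels: frozenset[int] | None = None  # default: two least urgent

    def __post_init__(self) -> None:
        if not 0 <= self.priority_criteria <= 100:
            raise ConfigError("priority_criteria must lie in [0, 100]")
        for level, value in self.thresholds.items():
            if level < 2:
                raise ConfigError("thresholds apply to ESI levels 2 and up")
            if not value > 0:
                raise ConfigError(f"threshold for ESI {level} must be > 0")
        if self.abandon_levels is None:
            worst = sorted(self.thresholds)[-2:] if len(self.thresholds) >= 2 else []
            self.abandon_levels = frozenset(worst)

    def threshold_for(self, esi: int) -> float:
        if esi <= 1:
            return 0.0  # ESI 1 is always overdue: immediate take-in-charge
        try:
            return self.thresholds[esi]
        except KeyError:
            raise ConfigError(f"no waiting threshold configured for ESI {esi}") from None


@dataclass
class QueueEntry:
    """A patient waiting at an activity.

    ``waiting_since`` is the instant the waiting clock started; thresholds
    measure time in the department, so the engine sets it to the patient's
    arrival time.
    """

    patient: Patient
    waiting_since: float
    activity: str


def _excess(entry: QueueEntry, params: PolicyParams, now: float) -> float:
    return (now - entry.waiting_since) - params.threshold_for(entry.patient.esi)


def overdue_patients(
    queue: list[QueueEntry], params: PolicyParams, now: float
) -> list[QueueEntry]:
    """Queue entries past their urgency-level threshold, most critical first.

    ESI-1 entries are always included and sort ahead of everything; the rest
    are ordered by ascending ESI, then by descending excess over threshold.
    """
    overdue = [
        e for e in queue if e.patient.esi == 1 or _excess(e, params, now) > 0
    ]
    overdue.sort(
        key=lambda e: (e.patient.esi, -_excess(e, params, now), e.patient.id)
    )
    return overdue


def select_next_patient(
    queue: list[QueueEntry],
    params: PolicyParams,
    now: float,
    rng: random.Random,
) -> QueueEntry | None:
    """Pick the next patient from a queue, or None when it is empty.

    Overdue patients (check-excess-time gateway) preempt the coin flip.
    Otherwise, with probability ``priority_criteria/100`` the most urgent
    patient is chosen (ties to the longest wait), else the longest-waiting
    one (ties to the most urgent).  Remaining ties break on patient id.
    """
    if not queue:
        return None
    overdue = overdue_patients(queue, params, now)
    if overdue:
        return overdue[0]
    if rng.random() * 100.0 < params.priority_criteria:
        key = lambda e: (e.patient.esi, e.waiting_since, e.patient.id)
    else:
        key = lambda e: (e.waiting_since, e.patient.esi, e.patient.id)
    return min(queue, key=key)


def should_abandon(
    entry: QueueEntry,
    queue_len: int,
    now: float,
    params: PolicyParams,
    rng: random.Random,
) -> bool:
    """One per-tick Bernoulli abandonment trial for a waiting patient."""
    patient = entry.patient
    if patient.esi not in params.abandon_levels:
        return False
    if patient.t_first_doctor is not None:
        return False
    if params.abandon_a0 == -math.inf:
        return False
    wait_hours = (now - patient.t_arrival) / 3600.0
    x = params.abandon_a0 + params.abandon_a1 * wait_hours + params.abandon_a2 * queue_len
    p = 1.0 / (1.0 + math.exp(-x))
    return rng.random() < p


def route_next(
    patient: Patient,
    graph: ProcessGraph,
    rng: random.Random,
    now: float | None = None,
) -> str | None:
    """Choose the patient's next activity after release from the current one.

    Arriving patients (no current location) are sent to the entry admitting
    their ESI level.  At an exit activity the patient is discharged: state and
    ``t_discharge`` are set and None is returned.  Otherwise a successor is
    drawn with probability proportional to routing weight among the arcs
    admitting the patient's level.
    """
    if patient.current_location is None:
        return graph.entry_for(patient.esi)
    here = graph.activities[patient.current_location]
    if here.is_exit:
        patient.state = "discharged"
        if now is not None:
            patient.t_discharge = now
        return None
    candidates = [
        a
        for a in graph.out_arcs(patient.current_location)
        if a.admits(patient.esi) and a.routing_weight > 0
    ]
    if not candidates:
        raise GraphValidationError(
            f"no admissible outgoing arc from {patient.current_location!r}"
            f" for ESI {patient.esi}"
        )
    total = sum(a.routing_weight for a in candidates)
    pick = rng.random() * total
    acc = 0.0
    for arc in candidates:
        acc += arc.routing_weight
        if pick < acc:
            return arc.dst
    return candidates[-1].dst
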