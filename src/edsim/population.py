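"""Patient arrivals and worker roster.

Daily arrival counts are Poisson with a weekday-dependent mean: if the
department sees ``daily_mean`` patients per day on average and weekday *d*
carries a fraction ``w_d`` of the weekly total, the Poisson mean for that
weekday is ``7 * daily_mean * w_d`` (so the weekly expectation is
``7 * daily_mean``).  Arrival instants are uniform within the day unless an
hourly profile is supplied.  Urgency (ESI) levels are drawn i.i.d. from a
configured mix, with level 1 the most urgent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .process_graph import ROLES, ProcessGraph

__all__ = [
    "WEEKDAYS",
    "DEFAULT_WEEKDAY_WEIGHTS",
    "DEFAULT_STAFFING",
    "Patient",
    "Worker",
    "ArrivalConfig",
    "ConfigError",
    "sample_daily_count",
    "sample_esi",
    "generate_day_arrivals",
    "roster_workers",
]

SECONDS_PER_DAY = 86_400

WEEKDAYS = (
    "monday",
    "tuesday",
    "wednesday",
    "thursday",
    "friday",
    "saturday",
    "sunday",
)

#: Observed 2019 weekday shares of arrivals (Monday and Friday peak).
DEFAULT_WEEKDAY_WEIGHTS = {
    "monday": 0.169,
    "tuesday": 0.150,
    "wednesday": 0.144,
    "thursday": 0.146,
    "friday": 0.153,
    "saturday": 0.124,
    "sunday": 0.114,
}

#: Case-study staffing: 7 ED nurses, 4 doctors, 2 triage nurses, 2 social workers.
DEFAULT_STAFFING = {"ed_nurse": 7, "doctor": 4, "triage_nurse": 2, "social_worker": 2}


class ConfigError(ValueError):
    """A configuration value violates its contract."""


@dataclass
class Patient:
    """A patient agent and its lifecycle timestamps (seconds from sim start)."""

    id: int
    esi: int
    t_arrival: float
    t_first_doctor: float | None = None
    t_discharge: float | None = None
    state: str = "walking"  # walking | waiting | in_service | discharged | abandoned
    next_task: str | None = None
    current_location: str | None = None
    # engine bookkeeping
    warmup: bool = False
    path: list[str] = field(default_factory=list)


@dataclass
class Worker:
    """A staff agent; ``skill`` scales service speed (2.0 = twice as fast)."""

    id: int
    role: str
    skill: float = 1.0
    state: str = "seeking"  # seeking | moving | waiting_to_start | busy
    busy_seconds: float = 0.0
    assigned_patient: int | None = None


def _weekday_name(weekday) -> str:
    if isinstance(weekday, str):
        name = weekday.lower()
        if name not in WEEKDAYS:
            raise ConfigError(f"unknown weekday {weekday!r}")
        return name
    idx = int(weekday)
    if not 0 <= idx <= 6:
        raise ConfigError(f"weekday index {weekday!r} outside 0..6 (0 = Monday)")
    return WEEKDAYS[idx]


@dataclass
class ArrivalConfig:
    """Stochastic arrival process parameters."""

    daily_mean: float = 125.0
    weekday_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WEEKDAY_WEIGHTS)
    )
    esi_mix: dict[int, float] = field(
        default_factory=lambda: {1: 0.02, 2: 0.13, 3: 0.40, 4: 0.30, 5: 0.15}
    )
    hourly_profile: list[float] | None = None

    def __post_init__(self) -> None:
        if not self.daily_mean >= 0:
            raise ConfigError("daily_mean must be >= 0")
        if set(self.weekday_weights) != set(WEEKDAYS):
            raise ConfigError("weekday_weights must name all seven weekdays")
        if abs(sum(self.weekday_weights.values()) - 1.0) > 1e-9:
            raise ConfigError("weekday_weights must sum to 1")
        if any(w < 0 for w in self.weekday_weights.values()):
            raise ConfigError("weekday_weights must be nonnegative")
        if abs(sum(self.esi_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("esi_mix must sum to 1")
        if any(p < 0 for p in self.esi_mix.values()):
            raise ConfigError("esi_mix probabilities must be nonnegative")
        if any(not isinstance(k, int) or k < 1 for k in self.esi_mix):
            raise ConfigError("esi_mix keys must be integer levels >= 1")
        if self.hourly_profile is not None:
            if len(self.hourly_profile) != 24:
                raise ConfigError("hourly_profile must have 24 entries")
            if any(w < 0 for w in self.hourly_profile):
                raise ConfigError("hourly_profile weights must be nonnegative")
            if sum(self.hourly_profile) <= 0:
                raise ConfigError("hourly_profile must have positive total weight")

    @property
    def levels(self) -> tuple[int, ...]:
        return tuple(sorted(self.esi_mix))


def sample_daily_count(weekday, cfg: ArrivalConfig, rng: np.random.Generator) -> int:
    """Poisson draw of the number of arrivals on the given weekday.

    The mean is ``7 * daily_mean * weekday_weight``, so weekly totals match
    ``7 * daily_mean`` while respecting the weekday pattern.
    """
    name = _weekday_name(weekday)
    lam = 7.0 * cfg.daily_mean * cfg.weekday_weights[name]
    return int(rng.poisson(lam))


def sample_esi(cfg: ArrivalConfig, rng: np.random.Generator) -> int:
    """Draw one urgency level from the configured mix."""
    levels = cfg.levels
    probs = np.array([cfg.esi_mix[l] for l in levels], dtype=float)
    probs = probs / probs.sum()
    return int(levels[rng.choice(len(levels), p=probs)])


def _arrival_seconds(n: int, cfg: ArrivalConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.hourly_profile is None:
        offsets = rng.uniform(0.0, SECONDS_PER_DAY, size=n)
    else:
        w = np.asarray(cfg.hourly_profile, dtype=float)
        hours = rng.choice(24, size=n, p=w / w.sum())
        offsets = hours * 3600.0 + rng.uniform(0.0, 3600.0, size=n)
    offsets.sort()
    return offsets


def generate_day_arrivals(
    day_index: int,
    cfg: ArrivalConfig,
    rng: np.random.Generator,
    start_id: int = 0,
    graph: ProcessGraph | None = None,
) -> list[Patient]:
    """Generate the patients arriving on simulation day ``day_index``.

    Day 0 is a Monday.  Arrival times are sorted and lie within the day's
    ``[day*86400, (day+1)*86400)`` window.  When a graph is given, each
    patient's ``next_task`` is set to the entry activity admitting its ESI
    level (so ESI-1 arrivals head straight for a Shock-Room entry).
    """
    weekday = WEEKDAYS[day_index % 7]
    n = sample_daily_count(weekday, cfg, rng)
    offsets = _arrival_seconds(n, cfg, rng)
    # one esi draw per patient, in arrival order
    levels = cfg.levels
    probs = np.array([cfg.esi_mix[l] for l in levels], dtype=float)
    probs = probs / probs.sum()
    esis = rng.choice(len(levels), size=n, p=probs)
    patients = []
    base = day_index * SECONDS_PER_DAY
    for i in range(n):
        esi = int(levels[esis[i]])
        p = Patient(id=start_id + i, esi=esi, t_arrival=base + float(offsets[i]))
        if graph is not None:
            p.next_task = graph.entry_for(esi)
        patients.append(p)
    return patients


def roster_workers(
    staffing: dict[str, int], skills: dict[str, float] | None = None
) -> list[Worker]:
    """Build the worker roster; ``skills`` optionally overrides per role."""
    skills = skills or {}
    for role in list(staffing) + list(skills):
        if role not in ROLES:
            raise ConfigError(f"unknown operator role {role!r}")
    workers: list[Worker] = []
    wid = 0
    for role in ROLES:
        count = int(staffing.get(role, 0))
        if count < 0:
            raise ConfigError(f"staffing for {role!r} must be >= 0")
        for _ in range(count):
            workers.append(Worker(id=wid, role=role, skill=float(skills.get(role, 1.0))))
            wid += 1
    return workers
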