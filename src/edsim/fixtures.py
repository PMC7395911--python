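"""Synthetic case-study fixtures.

The real department's process graph (service durations, routing fractions)
is not public, so every test and demo runs on a synthetic emulation of the
case study: a Registration-Triage-Visit backbone with exam services
(blood analysis, radiology, imaging), medical consultancy, a Shock-Room
entry reserved for ESI-1 arrivals, about 125 arrivals per day with the 2019
weekday pattern, and a 7/4/2/2 staffing of ED nurses, doctors, triage
nurses, and social workers.

All service durations and routing weights here are SYNTHETIC defaults chosen
to be plausible for a mid-size department; they are not the hospital's
values.  Three load presets scale the service durations:

* ``light``    — ample capacity, essentially no queueing;
* ``realistic``— moderate utilization, occasional queues;
* ``stressed`` — rush-hour queueing heavy enough that waits routinely cross
  the policy thresholds, so the patient-selection policy visibly matters.

Arrivals follow a peaked intraday profile (nighttime trough, late-morning
peak), as in observed ED arrival curves; the daily counts and weekday
pattern come from the case study.
"""

from __future__ import annotations

from dataclasses import dataclass

from .engine import SimConfig
from .policy import DEFAULT_THRESHOLD_BOUNDS, PolicyParams
from .population import DEFAULT_STAFFING, ArrivalConfig, ConfigError
from .process_graph import Activity, Arc, ProcessGraph

__all__ = ["FixtureSpec", "build_fixture_graph", "build_fixture_config", "LOAD_PRESETS"]

#: Service-duration multiplier per load preset.
LOAD_PRESETS = {"light": 0.6, "realistic": 1.0, "stressed": 1.4}

#: Synthetic ESI mixes (fractions of arrivals per urgency level); like real
#: triage distributions they are dominated by the low-urgency codes.
ESI_MIX = {
    4: {1: 0.02, 2: 0.15, 3: 0.58, 4: 0.25},
    5: {1: 0.02, 2: 0.08, 3: 0.20, 4: 0.45, 5: 0.25},
}

#: Synthetic within-day arrival weights per hour (normalized at use):
#: quiet nights, late-morning peak, long afternoon plateau.
HOURLY_PROFILE = [
    2.0, 1.5, 1.0, 1.0, 1.0, 1.5, 2.0, 3.0,
    5.0, 7.0, 8.0, 8.0, 7.0, 6.0, 6.0, 6.0,
    6.0, 6.0, 5.5, 5.0, 4.5, 4.0, 3.0, 2.5,
]


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the synthetic case study."""

    scale: float = 1.0  # multiplies the 125/day arrival mean
    seed: int = 0
    levels: int = 5  # 4- or 5-level urgency scale
    load: str = "realistic"

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ConfigError("scale must be > 0")
        if self.levels not in (4, 5):
            raise ConfigError("levels must be 4 or 5")
        if self.load not in LOAD_PRESETS:
            raise ConfigError(f"load must be one of {sorted(LOAD_PRESETS)}")


def build_fixture_graph(spec: FixtureSpec = FixtureSpec()) -> ProcessGraph:
    """Synthetic ED process graph emulating the case study's structure."""
    m = LOAD_PRESETS[spec.load]
    levels = frozenset(range(2, spec.levels + 1))

    def act(name, roles, mean, sd, **kw):
        return Activity(
            name=name, roles=roles, service_mean=mean * m, service_sd=sd * m, **kw
        )

    activities = [
        act("Registration", ("social_worker",), 240, 60, is_entry=True, entry_esi=levels),
        act("Triage", ("triage_nurse",), 300, 120),
        act("Visit", ("doctor", "ed_nurse"), 900, 300),
        act("Blood-analysis", ("ed_nurse",), 600, 180),
        act("Radiology", ("ed_nurse",), 900, 240),
        act("Imaging", ("ed_nurse",), 1200, 300),
        act("Consultancy", ("doctor",), 900, 300),
        act(
            "Shock-Room",
            ("doctor", "ed_nurse"),
            2700,
            600,
            is_entry=True,
            entry_esi=frozenset({1}),
        ),
        # exit node; its service parameters are placeholders, never used
        Activity("Discharge", ("ed_nurse",), 60.0, 0.0, is_exit=True),
    ]
    arcs = [
        Arc("Registration", "Triage", 30),
        Arc("Triage", "Visit", 60),
        Arc("Visit", "Discharge", 60, routing_weight=0.45),
        Arc("Visit", "Blood-analysis", 60, routing_weight=0.25),
        Arc("Visit", "Radiology", 90, routing_weight=0.12),
        Arc("Visit", "Imaging", 90, routing_weight=0.08),
        Arc("Visit", "Consultancy", 60, routing_weight=0.10),
        Arc("Blood-analysis", "Discharge", 60),
        Arc("Radiology", "Discharge", 60),
        Arc("Imaging", "Discharge", 60),
        Arc("Consultancy", "Discharge", 60),
        Arc("Shock-Room", "Discharge", 60),
    ]
    return ProcessGraph(
        activities={a.name: a for a in activities}, arcs=arcs
    )


def build_fixture_config(
    spec: FixtureSpec = FixtureSpec(),
) -> tuple[ArrivalConfig, dict[str, int], PolicyParams, SimConfig]:
    """Arrivals, staffing, policy and simulation config for the case study.

    Weekday weights are the observed 2019 shares; the daily mean is
    ``125 * scale`` (the reported yearly total ~47,000 implies ~129/day —
    the round daily figure is used).  Thresholds default to the midpoints of
    their clinical search bounds; priority-criteria starts at 50; the
    simulated span is one warm-up day plus four weeks.
    """
    arrivals = ArrivalConfig(
        daily_mean=125.0 * spec.scale,
        esi_mix=dict(ESI_MIX[spec.levels]),
        hourly_profile=list(HOURLY_PROFILE),
    )
    staffing = dict(DEFAULT_STAFFING)
    thresholds = {
        l: (lo + hi) / 2
        for l, (lo, hi) in DEFAULT_THRESHOLD_BOUNDS.items()
        if l <= spec.levels
    }
    policy = PolicyParams(
        priority_criteria=50,
        thresholds=thresholds,
        # mild, always-on abandonment hazard for the two least urgent levels:
        # ~0.3%/tick at a 3 h wait in a 20-patient queue (tick = 60 s)
        abandon_a0=-8.0,
        abandon_a1=0.5,
        abandon_a2=0.03,
    )
    sim = SimConfig(horizon_days=28, warmup_days=1, tick_seconds=60, seed=spec.seed)
    return arrivals, staffing, policy, sim
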