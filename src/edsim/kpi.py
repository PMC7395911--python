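"""Performance indicators of a simulation run.

Two leading indicators are reported per urgency level, in minutes:

* **DTDT** (Door-to-Doctor-Time): admission to first contact with a doctor.
* **LoS** (Length of Stay): arrival to discharge.

Per-role utilization is the fraction of scheduled time spent working directly
with patients.  The **Quality Score (QS)** is the objective the optimizer
minimizes: for each urgency level 2..L, count the patients whose wait for a
doctor exceeded that level's threshold (abandoned patients always count, since
they were never served in time), square the count, and sum.  ESI-1 patients
are excluded — they are taken in charge immediately by construction.  A
two-group variant squares the totals of the urgent (upper) and less-critical
(lower) halves of the scale instead of each level.

Warm-up patients are excluded from every indicator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .engine import RunResult
from .population import ConfigError

__all__ = [
    "KpiReport",
    "GroupStats",
    "compute_dtdt",
    "compute_los",
    "compute_utilization",
    "quality_score",
    "build_report",
]


@dataclass(frozen=True)
class GroupStats:
    """Mean/sd (minutes) and count for one ESI level's indicator values."""

    mean: float | None
    sd: float | None
    n: int


def _stats(values: list[float]) -> GroupStats:
    n = len(values)
    if n == 0:
        return GroupStats(mean=None, sd=None, n=0)
    mean = sum(values) / n
    if n == 1:
        return GroupStats(mean=mean, sd=0.0, n=1)
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return GroupStats(mean=mean, sd=math.sqrt(var), n=n)


def _by_esi(result: RunResult, value) -> dict[int, GroupStats]:
    groups: dict[int, list[float]] = {}
    for p in result.kpi_patients():
        v = value(p)
        if v is not None:
            groups.setdefault(p.esi, []).append(v)
    levels = sorted({p.esi for p in result.kpi_patients()} | set(groups))
    return {esi: _stats(groups.get(esi, [])) for esi in levels}


def compute_dtdt(result: RunResult) -> dict[int, GroupStats]:
    """Door-to-Doctor-Time per ESI level, minutes.

    Patients never seen by a doctor (abandoned or exam-only paths) are
    excluded; empty levels report count 0 with unset mean.
    """
    return _by_esi(
        result,
        lambda p: (p.t_first_doctor - p.t_arrival) / 60.0
        if p.t_first_doctor is not None
        else None,
    )


def compute_los(result: RunResult) -> dict[int, GroupStats]:
    """Length of Stay per ESI level, minutes, over discharged patients."""
    return _by_esi(
        result,
        lambda p: (p.t_discharge - p.t_arrival) / 60.0
        if p.state == "discharged" and p.t_discharge is not None
        else None,
    )


def compute_utilization(result: RunResult, role: str) -> float | None:
    """Fraction of scheduled time the role's workers spent with patients."""
    staff = [w for w in result.workers if w.role == role]
    if not staff:
        return None
    busy = sum(w.busy_seconds for w in staff)
    scheduled = result.scheduled_seconds * len(staff)
    return busy / scheduled if scheduled > 0 else 0.0


def _exceeded(p, thresholds: dict[int, float], sim_end: float) -> bool:
    try:
        threshold = thresholds[p.esi]
    except KeyError:
        raise ConfigError(f"no QS threshold for ESI level {p.esi}") from None
    if p.state == "abandoned":
        return True  # never served in time, by definition
    if p.t_first_doctor is not None:
        return (p.t_first_doctor - p.t_arrival) > threshold
    # still in the system (or discharged without a doctor) at the horizon:
    # exceeded only if the wait had already passed the threshold
    end = p.t_discharge if p.t_discharge is not None else sim_end
    return (end - p.t_arrival) > threshold


def quality_score(
    result: RunResult,
    thresholds: dict[int, float],
    mode: str = "per_level",
) -> float:
    """Quality Score: lower is better, 0 when every wait met its threshold.

    ``mode="per_level"`` (default) sums squared exceedance counts per ESI
    level; ``mode="two_group"`` squares the urgent-half and less-critical-half
    totals instead.
    """
    if mode not in ("per_level", "two_group"):
        raise ValueError(f"unknown QS mode {mode!r}")
    counts: dict[int, int] = {}
    for p in result.kpi_patients():
        if p.esi <= 1:
            continue
        if _exceeded(p, thresholds, result.sim_end):
            counts[p.esi] = counts.get(p.esi, 0) + 1
    if mode == "per_level":
        return float(sum(c * c for c in counts.values()))
    levels = sorted(thresholds)
    lower_half = set(levels[len(levels) // 2 :])  # the least urgent half
    urgent = sum(c for l, c in counts.items() if l not in lower_half)
    less = sum(c for l, c in counts.items() if l in lower_half)
    return float(urgent * urgent + less * less)


@dataclass
class KpiReport:
    """Aggregated indicators of one run."""

    dtdt: dict[int, GroupStats]
    los: dict[int, GroupStats]
    utilization: dict[str, float | None]
    abandoned: int
    abandonment_rate: float
    quality_score: float
    dispositions: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for esi, st in self.dtdt.items():
            rows.append(("dtdt_min", str(esi), st.mean, st.sd, st.n))
        for esi, st in self.los.items():
            rows.append(("los_min", str(esi), st.mean, st.sd, st.n))
        for role, u in self.utilization.items():
            rows.append(("utilization", role, u, None, None))
        rows.append(("abandonment_rate", "all", self.abandonment_rate, None, self.abandoned))
        rows.append(("quality_score", "all", self.quality_score, None, None))
        return pd.DataFrame(rows, columns=["indicator", "esi_or_role", "mean", "sd", "n"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> str:
        lines = ["KPI summary (non-warm-up patients)"]
        for esi in sorted(self.dtdt):
            d, l = self.dtdt[esi], self.los.get(esi, GroupStats(None, None, 0))
            lines.append(
                f"  ESI {esi}: DTDT {_fmt(d.mean)} min (sd {_fmt(d.sd)}, n={d.n});"
                f" LoS {_fmt(l.mean)} min (sd {_fmt(l.sd)}, n={l.n})"
            )
        for role, u in self.utilization.items():
            lines.append(
                f"  utilization[{role}]: " + ("n/a" if u is None else f"{100 * u:.1f}%")
            )
        lines.append(
            f"  abandoned: {self.abandoned} ({100 * self.abandonment_rate:.2f}%)"
        )
        lines.append(f"  quality score: {self.quality_score:.0f}")
        d = self.dispositions
        lines.append(
            f"  dispositions: {d.get('discharged', 0)} discharged,"
            f" {d.get('abandoned', 0)} abandoned, {d.get('in_system', 0)} in system"
            f" of {d.get('arrivals', 0)} arrivals"
        )
        return "\n".join(lines)


def _fmt(x: float | None) -> str:
    return "n/a" if x is None else f"{x:.1f}"


def build_report(
    result: RunResult,
    thresholds: dict[int, float] | None = None,
    qs_mode: str = "per_level",
) -> KpiReport:
    """Compute the full KPI report for a run.

    ``thresholds`` defaults to the policy thresholds echoed in the run config.
    """
    if thresholds is None:
        thresholds = result.config.get("thresholds")
        if not thresholds:
            raise ConfigError("no thresholds available for the quality score")
    kpi_pat = result.kpi_patients()
    abandoned = sum(1 for p in kpi_pat if p.state == "abandoned")
    rate = abandoned / len(kpi_pat) if kpi_pat else 0.0
    roles = sorted({w.role for w in result.workers})
    from collections import Counter

    c = Counter(p.state for p in kpi_pat)
    dispositions = {
        "arrivals": len(kpi_pat),
        "discharged": c.get("discharged", 0),
        "abandoned": c.get("abandoned", 0),
        "in_system": len(kpi_pat) - c.get("discharged", 0) - c.get("abandoned", 0),
    }
    return KpiReport(
        dtdt=compute_dtdt(result),
        los=compute_los(result),
        utilization={r: compute_utilization(result, r) for r in roles},
        abandoned=abandoned,
        abandonment_rate=rate,
        quality_score=quality_score(result, thresholds, mode=qs_mode),
        dispositions=dispositions,
    )
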