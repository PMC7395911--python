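"""Structured-text (YAML) configuration for the command-line interface.

One file holds sections ``arrivals``, ``staffing``, ``skills``, ``policy``,
``sim``, ``sweep`` and ``ga``, plus a ``graph`` path to a GraphML process
graph.  Every section is optional: missing values fall back to the synthetic
case-study defaults, so an empty file is a runnable configuration (with the
fixture graph).  Threshold keys are spelled ``esi2`` .. ``esi5`` and given in
seconds.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

from .engine import SimConfig
from .fixtures import FixtureSpec, build_fixture_config, build_fixture_graph
from .optimize import GAConfig, GeneSpec, default_gene_specs
from .policy import DEFAULT_THRESHOLD_BOUNDS, PolicyParams
from .population import ArrivalConfig, ConfigError
from .process_graph import ProcessGraph, load_graphml

__all__ = ["Scenario", "load_config", "config_hash", "write_default_config"]


@dataclass
class Scenario:
    """Everything one simulation (or search) needs, parsed and validated."""

    graph: ProcessGraph
    arrivals: ArrivalConfig
    staffing: dict[str, int]
    skills: dict[str, float] | None
    policy: PolicyParams
    sim: SimConfig
    sweep: dict | None
    ga: dict | None
    raw: dict


def _section(data: dict, name: str) -> dict:
    value = data.get(name) or {}
    if not isinstance(value, dict):
        raise ConfigError(f"config section {name!r} must be a mapping")
    return value


def _parse_thresholds(raw: dict) -> dict[int, float]:
    out = {}
    for key, value in raw.items():
        name = str(key).lower()
        if not name.startswith("esi"):
            raise ConfigError(f"threshold key {key!r} must look like 'esi2'")
        level = int(name.removeprefix("esi"))
        out[level] = math.inf if str(value) in ("inf", ".inf") else float(value)
    return out


def _parse_policy(data: dict, defaults: PolicyParams) -> PolicyParams:
    sec = _section(data, "policy")
    thresholds = dict(defaults.thresholds)
    if "thresholds" in sec:
        thresholds.update(_parse_thresholds(sec["thresholds"]))
    ab = sec.get("abandonment") or {}
    a0 = ab.get("a0", defaults.abandon_a0)
    levels = ab.get("levels")
    return PolicyParams(
        priority_criteria=int(sec.get("priority_criteria", defaults.priority_criteria)),
        thresholds=thresholds,
        abandon_a0=-math.inf if a0 in ("-inf", "off", None) and "a0" in ab else float(a0),
        abandon_a1=float(ab.get("a1", defaults.abandon_a1)),
        abandon_a2=float(ab.get("a2", defaults.abandon_a2)),
        abandon_levels=frozenset(int(l) for l in levels) if levels else None,
    )


def _parse_arrivals(data: dict, defaults: ArrivalConfig) -> ArrivalConfig:
    sec = _section(data, "arrivals")
    weights = {
        str(k).lower(): float(v)
        for k, v in (sec.get("weekday_weights") or defaults.weekday_weights).items()
    }
    mix = {int(k): float(v) for k, v in (sec.get("esi_mix") or defaults.esi_mix).items()}
    profile = sec.get("hourly_profile", defaults.hourly_profile)
    return ArrivalConfig(
        daily_mean=float(sec.get("daily_mean", defaults.daily_mean)),
        weekday_weights=weights,
        esi_mix=mix,
        hourly_profile=list(profile) if profile is not None else None,
    )


def _parse_sim(data: dict, defaults: SimConfig) -> SimConfig:
    sec = _section(data, "sim")
    try:
        return SimConfig(
            horizon_days=int(sec.get("horizon_days", defaults.horizon_days)),
            warmup_days=int(sec.get("warmup_days", defaults.warmup_days)),
            tick_seconds=int(sec.get("tick_seconds", defaults.tick_seconds)),
            seed=int(sec.get("seed", defaults.seed)),
            replicate_count=int(sec.get("replicates", defaults.replicate_count)),
        )
    except ValueError as exc:
        raise ConfigError(f"sim: {exc}") from exc


def parse_gene_specs(names: list[str] | None, levels: int = 5) -> tuple[GeneSpec, ...]:
    """Resolve gene names against the default five-dimensional space."""
    available = {s.name: s for s in default_gene_specs(range(2, levels + 1))}
    if not names:
        return tuple(available.values())
    specs = []
    for name in names:
        if name not in available:
            raise ConfigError(
                f"unknown gene {name!r}; expected one of {sorted(available)}"
            )
        specs.append(available[name])
    return tuple(specs)


def load_config(path: str | Path | None) -> Scenario:
    """Parse a YAML config file into a validated scenario.

    ``path=None`` yields the pure synthetic case-study defaults.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
    spec = FixtureSpec(levels=int(data.get("levels", 5)), load=str(data.get("load", "realistic")))
    d_arr, d_staff, d_pol, d_sim = build_fixture_config(spec)
    if data.get("graph"):
        graph = load_graphml(data["graph"])
    else:
        graph = build_fixture_graph(spec)
    staffing = {str(k): int(v) for k, v in (_section(data, "staffing") or d_staff).items()}
    skills_sec = _section(data, "skills")
    skills = {str(k): float(v) for k, v in skills_sec.items()} or None
    return Scenario(
        graph=graph,
        arrivals=_parse_arrivals(data, d_arr),
        staffing=staffing,
        skills=skills,
        policy=_parse_policy(data, d_pol),
        sim=_parse_sim(data, d_sim),
        sweep=data.get("sweep"),
        ga=data.get("ga"),
        raw=data,
    )


def config_hash(scenario: Scenario) -> str:
    """Stable short hash of the raw configuration, for run logging."""
    blob = yaml.safe_dump(scenario.raw, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_default_config(path: str | Path, spec: FixtureSpec = FixtureSpec()) -> None:
    """Emit a fully explicit config matching the synthetic case study."""
    arrivals, staffing, policy, sim = build_fixture_config(spec)
    data = {
        "levels": spec.levels,
        "load": spec.load,
        "graph": "fixture.graphml",
        "arrivals": {
            "daily_mean": arrivals.daily_mean,
            "weekday_weights": dict(arrivals.weekday_weights),
            "esi_mix": dict(arrivals.esi_mix),
        },
        "staffing": dict(staffing),
        "policy": {
            "priority_criteria": policy.priority_criteria,
            "thresholds": {f"esi{l}": v for l, v in sorted(policy.thresholds.items())},
            "abandonment": {
                "a0": policy.abandon_a0,
                "a1": policy.abandon_a1,
                "a2": policy.abandon_a2,
                "levels": sorted(policy.abandon_levels),
            },
        },
        "sim": {
            "horizon_days": sim.horizon_days,
            "warmup_days": sim.warmup_days,
            "tick_seconds": sim.tick_seconds,
            "seed": sim.seed,
            "replicates": sim.replicate_count,
        },
        "sweep": {
            "parameter": "priority_criteria",
            "lower": 0,
            "upper": 100,
            "step": 5,
            "replicates": 10,
            "seed": 0,
        },
        "ga": {
            "genes": [s.name for s in default_gene_specs(range(2, spec.levels + 1))],
            "population_size": 100,
            "crossover_rate": 0.7,
            "mutation_rate": 0.3,
            "generations": 20,
            "elitism": 1,
            "tournament_size": 2,
            "replicates": 5,
            "seed": 0,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
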