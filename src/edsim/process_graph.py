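"""Emergency-department process graphs.

An ED process is a weighted directed graph whose nodes are *activities*
(registration, triage, doctor visit, exams, ...) and whose arcs are patient
walks between activities.  Each activity states how many operators it seizes,
which roles they must have, and the mean/sd of its service duration.  Each arc
carries the average walk duration, a routing weight, and an optional filter on
the urgency (ESI) levels allowed to take it.

Graphs are read from and written to GraphML so they can be edited with any
standard graph tool.  All durations are stored in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx

__all__ = [
    "ROLES",
    "Activity",
    "Arc",
    "ProcessGraph",
    "SchemaError",
    "GraphValidationError",
    "load_graphml",
    "write_graphml",
    "validate",
]

#: Operator roles recognised by the simulator.
ROLES = ("doctor", "ed_nurse", "triage_nurse", "social_worker")

#: Required GraphML node keys (the optional "esi" entry filter is extra).
NODE_KEYS = ("name", "operators", "role", "dur_mean_s", "dur_sd_s", "entry", "exit")
#: GraphML edge keys; "weight" and "esi" are optional with defaults.
EDGE_KEYS = ("walk_s",)


class SchemaError(ValueError):
    """A GraphML file is missing a required key or holds a malformed value."""


class GraphValidationError(ValueError):
    """A structurally well-formed graph violates a process-graph invariant."""


def _parse_esi_set(raw: str | None) -> frozenset[int] | None:
    if raw is None or str(raw).strip() == "":
        return None
    return frozenset(int(tok) for tok in str(raw).split(","))


def _esi_str(levels: frozenset[int] | None) -> str:
    return "" if levels is None else ",".join(str(v) for v in sorted(levels))


@dataclass(frozen=True)
class Activity:
    """One node of the process graph.

    ``roles`` lists the role of each operator the activity seizes, so its
    length equals the number of operators required.  A two-person visit by a
    doctor and a nurse is ``roles=("doctor", "ed_nurse")``.
    """

    name: str
    roles: tuple[str, ...]
    service_mean: float  # seconds
    service_sd: float  # seconds
    is_entry: bool = False
    is_exit: bool = False
    #: For entry activities: urgency levels admitted here (None = any).
    entry_esi: frozenset[int] | None = None

    @property
    def operators_required(self) -> int:
        return len(self.roles)


@dataclass(frozen=True)
class Arc:
    """A directed walk between two activities."""

    src: str
    dst: str
    walk_seconds: float
    routing_weight: float = 1.0
    #: Urgency levels allowed on this arc (None = all levels).
    esi_filter: frozenset[int] | None = None

    def admits(self, esi: int) -> bool:
        return self.esi_filter is None or esi in self.esi_filter


@dataclass
class ProcessGraph:
    """Validated collection of activities and arcs."""

    activities: dict[str, Activity] = field(default_factory=dict)
    arcs: list[Arc] = field(default_factory=list)

    # -- views -------------------------------------------------------------

    def out_arcs(self, name: str) -> list[Arc]:
        return [a for a in self.arcs if a.src == name]

    @property
    def entries(self) -> list[Activity]:
        return [a for a in self.activities.values() if a.is_entry]

    @property
    def exits(self) -> list[Activity]:
        return [a for a in self.activities.values() if a.is_exit]

    def max_esi_level(self) -> int:
        """Largest urgency level mentioned anywhere in the graph (>= 1)."""
        seen = {1}
        for act in self.activities.values():
            if act.entry_esi:
                seen |= act.entry_esi
        for arc in self.arcs:
            if arc.esi_filter:
                seen |= arc.esi_filter
        return max(seen)

    def entry_for(self, esi: int) -> str:
        """Entry activity admitting urgency level ``esi``.

        The most specific admitting entry wins (smallest admitted set;
        an unrestricted entry admits everything).  This is how ESI-1
        arrivals bypass registration into a Shock-Room entry.
        """
        candidates = [
            e for e in self.entries if e.entry_esi is None or esi in e.entry_esi
        ]
        if not candidates:
            raise GraphValidationError(f"no entry activity admits ESI level {esi}")
        candidates.sort(
            key=lambda e: (
                len(e.entry_esi) if e.entry_esi is not None else math.inf,
                e.name,
            )
        )
        return candidates[0].name

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProcessGraph):
            return NotImplemented
        return self.activities == other.activities and sorted(
            self.arcs, key=lambda a: (a.src, a.dst)
        ) == sorted(other.arcs, key=lambda a: (a.src, a.dst))

    # -- validation --------------------------------------------------------

    def validate(self) -> list[str]:
        return validate(self)


def _reachable_from_entries(graph: ProcessGraph) -> set[str]:
    frontier = [a.name for a in graph.entries]
    seen = set(frontier)
    while frontier:
        node = frontier.pop()
        for arc in graph.out_arcs(node):
            if arc.dst in graph.activities and arc.dst not in seen:
                seen.add(arc.dst)
                frontier.append(arc.dst)
    return seen


def _reaches_exit(graph: ProcessGraph) -> set[str]:
    preds: dict[str, set[str]] = {n: set() for n in graph.activities}
    for arc in graph.arcs:
        if arc.src in preds and arc.dst in preds:
            preds[arc.dst].add(arc.src)
    frontier = [a.name for a in graph.exits]
    seen = set(frontier)
    while frontier:
        node = frontier.pop()
        for p in preds[node]:
            if p not in seen:
                seen.add(p)
                frontier.append(p)
    return seen


def _levels_reaching(graph: ProcessGraph) -> dict[str, set[int]]:
    """Urgency levels that can be present at each node, flowing from entries."""
    levels = set(range(1, graph.max_esi_level() + 1))
    at: dict[str, set[int]] = {n: set() for n in graph.activities}
    frontier: list[str] = []
    for e in graph.entries:
        admitted = set(e.entry_esi) if e.entry_esi is not None else set(levels)
        at[e.name] |= admitted
        frontier.append(e.name)
    while frontier:
        node = frontier.pop()
        for arc in graph.out_arcs(node):
            if arc.dst not in at or arc.routing_weight <= 0:
                continue
            passed = at[node] if arc.esi_filter is None else at[node] & arc.esi_filter
            new = passed - at[arc.dst]
            if new:
                at[arc.dst] |= new
                frontier.append(arc.dst)
    return at


def validate(graph: ProcessGraph) -> list[str]:
    """Return a list of human-readable invariant violations (empty = valid)."""
    out: list[str] = []
    if not graph.activities:
        out.append("graph has no activities")
        return out
    for name, act in graph.activities.items():
        if act.name != name:
            out.append(f"activity keyed {name!r} has mismatched name {act.name!r}")
        if act.operators_required < 1:
            out.append(f"activity {name!r}: operators_required must be >= 1")
        for role in act.roles:
            if role not in ROLES:
                out.append(f"activity {name!r}: unknown role {role!r}")
        if not act.service_mean > 0:
            out.append(f"activity {name!r}: service_mean must be > 0")
        if act.service_sd < 0:
            out.append(f"activity {name!r}: service_sd must be >= 0")
    for arc in graph.arcs:
        tag = f"arc {arc.src!r}->{arc.dst!r}"
        if arc.src not in graph.activities:
            out.append(f"{tag}: source names a nonexistent activity")
        if arc.dst not in graph.activities:
            out.append(f"{tag}: target names a nonexistent activity")
        if arc.walk_seconds < 0:
            out.append(f"{tag}: walk_seconds must be >= 0")
        if arc.routing_weight < 0:
            out.append(f"{tag}: routing_weight must be >= 0")
    if out:
        return out  # structural errors make the flow checks meaningless
    if not graph.entries:
        out.append("graph has no entry activity")
    if not graph.exits:
        out.append("graph has no exit activity")
    if out:
        return out
    reachable = _reachable_from_entries(graph)
    for name in graph.activities:
        if name not in reachable:
            out.append(f"activity {name!r} unreachable from any entry")
    exiting = _reaches_exit(graph)
    for name in graph.activities:
        if name not in exiting:
            out.append(f"no exit reachable from activity {name!r}")
    # routing completeness: any urgency level present at a non-exit node must
    # have at least one positive-weight admissible arc out of it
    at = _levels_reaching(graph)
    for name, act in graph.activities.items():
        if act.is_exit:
            continue
        for esi in sorted(at[name]):
            total = sum(
                a.routing_weight
                for a in graph.out_arcs(name)
                if a.admits(esi) and a.routing_weight > 0
            )
            if total <= 0:
                out.append(
                    f"activity {name!r}: no admissible outgoing arc for ESI {esi}"
                )
    return out


# -- GraphML I/O ------------------------------------------------------------


def _roles_from_strings(role_raw: str, operators: int, node: str) -> tuple[str, ...]:
    parts = tuple(tok.strip() for tok in str(role_raw).split(",") if tok.strip())
    if not parts:
        raise SchemaError(f"node {node!r}: empty \"role\" value")
    if len(parts) == 1:
        return parts * operators
    if len(parts) != operators:
        raise SchemaError(
            f"node {node!r}: \"role\" lists {len(parts)} roles but"
            f" \"operators\" is {operators}"
        )
    return parts


def _to_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in {"1", "true", "yes"}


def load_graphml(path) -> ProcessGraph:
    """Load and validate a process graph from a GraphML file.

    Raises :class:`SchemaError` when a required key is absent and
    :class:`GraphValidationError` when the graph violates an invariant.
    """
    try:
        g = nx.read_graphml(path)
    except Exception as exc:  # malformed XML / GraphML
        raise SchemaError(f"cannot parse GraphML file {path!r}: {exc}") from exc
    graph = ProcessGraph()
    for node, data in g.nodes(data=True):
        for key in NODE_KEYS:
            if key not in data:
                raise SchemaError(f"node {node!r}: missing required key \"{key}\"")
        operators = int(data["operators"])
        roles = _roles_from_strings(data["role"], max(operators, 1), str(node))
        act = Activity(
            name=str(data["name"]),
            roles=roles if operators >= 1 else (),
            service_mean=float(data["dur_mean_s"]),
            service_sd=float(data["dur_sd_s"]),
            is_entry=_to_bool(data["entry"]),
            is_exit=_to_bool(data["exit"]),
            entry_esi=_parse_esi_set(data.get("esi")),
        )
        if operators < 1:
            # keep an invalid-but-representable activity; validate() reports it
            act = replace(act, roles=())
        graph.activities[act.name] = act
    for src, dst, data in g.edges(data=True):
        for key in EDGE_KEYS:
            if key not in data:
                raise SchemaError(
                    f"edge {src!r}->{dst!r}: missing required key \"{key}\""
                )
        src_name = str(g.nodes[src].get("name", src))
        dst_name = str(g.nodes[dst].get("name", dst))
        graph.arcs.append(
            Arc(
                src=src_name,
                dst=dst_name,
                walk_seconds=float(data["walk_s"]),
                routing_weight=float(data.get("weight", 1.0)),
                esi_filter=_parse_esi_set(data.get("esi")),
            )
        )
    violations = validate(graph)
    if violations:
        raise GraphValidationError("; ".join(violations))
    return graph


def write_graphml(graph: ProcessGraph, path) -> None:
    """Write a valid process graph to GraphML; re-loading yields an equal graph."""
    violations = validate(graph)
    if violations:
        raise GraphValidationError("; ".join(violations))
    g = nx.DiGraph()
    for act in graph.activities.values():
        attrs = {
            "name": act.name,
            "operators": act.operators_required,
            "role": ",".join(act.roles),
            "dur_mean_s": float(act.service_mean),
            "dur_sd_s": float(act.service_sd),
            "entry": bool(act.is_entry),
            "exit": bool(act.is_exit),
        }
        if act.entry_esi is not None:
            attrs["esi"] = _esi_str(act.entry_esi)
        g.add_node(act.name, **attrs)
    for arc in graph.arcs:
        attrs = {"walk_s": float(arc.walk_seconds), "weight": float(arc.routing_weight)}
        if arc.esi_filter is not None:
            attrs["esi"] = _esi_str(arc.esi_filter)
        g.add_edge(arc.src, arc.dst, **attrs)
    nx.write_graphml(g, path)
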