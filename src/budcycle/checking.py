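"""Checkpoint properties, hazard detection with counterexamples, SMV export.

Checkpoint conditions of the yeast cell cycle are encoded as two property
shapes over the asynchronous state graph:

* :class:`PrecedenceProperty` — on every path from the initial state, the
  consequent node may reach its level only at or after the instant the
  antecedent node first reaches its own (e.g. "Clb2 activation precedes
  Cdc20 activation", the M-metaphase checkpoint).
* :class:`ResponseProperty` — from every reachable state satisfying the
  trigger, every *fair* path eventually satisfies the obligation (e.g.
  "once Cdc20 is active, Swi5 eventually reaches its top level", the
  M-telophase checkpoint).

Fairness reduction
------------------
The SMV encoding of asynchrony uses a control variable choosing which
node's rule fires; fairness demands every node be chosen infinitely
often.  A chosen node whose update is a no-op merely stutters, so
fairness forces progress only through nodes whose update would change
value.  On a finite graph every infinite run eventually stays inside one
strongly connected component of the value-changing graph, and such a
suffix can be fair iff the component is *fair-sustainable*: for every
node there is some component state where its update is a no-op, or an
update edge that stays inside the component.  (A component that keeps
some node enabled with all its update edges leaving the component cannot
be looped fairly — scheduling that node ejects the run.)  "All fair
paths eventually reach T" therefore reduces to: no reachable absorbing
state other than T, and no reachable fair-sustainable component avoiding
T.  This replaces fair-CTL machinery with SCC analysis plus a local
no-op test; the reduction is specific to this encoding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import networkx as nx

from .dynamics import Trajectory, async_successors, is_fixed_point, local_target
from .netdef import CANONICAL_NODES, NetworkModel, State
from .statespace import DEFAULT_STATE_CAP, reachable_graph

__all__ = [
    "PrecedenceProperty",
    "ResponseProperty",
    "GlobalAttractorProperty",
    "PropertyVerdict",
    "check_precedence",
    "check_response",
    "check_global_attractor",
    "check_property",
    "check_all",
    "default_property_set",
    "load_property_set",
    "export_nusmv",
]


@dataclass(frozen=True)
class PrecedenceProperty:
    """``consequent`` may rise to its level only after ``antecedent`` has."""

    antecedent: tuple[str, int]
    consequent: tuple[str, int]
    name: str
    group: str = ""


@dataclass(frozen=True)
class ResponseProperty:
    """Every fair path from a trigger state eventually meets the obligation.

    ``obligation`` is either a ``(node, level)`` pair or the name of one of
    the model's reference states (e.g. ``"stationary_g1"``).
    """

    trigger: tuple[str, int]
    obligation: tuple[str, int] | str
    name: str
    group: str = ""


@dataclass(frozen=True)
class GlobalAttractorProperty:
    """Every fair path from the initial state ends at the target state."""

    target: str  # reference-state name
    name: str
    group: str = ""


Property = PrecedenceProperty | ResponseProperty | GlobalAttractorProperty


@dataclass
class PropertyVerdict:
    property_name: str
    group: str
    status: str  # "pass" | "fail"
    counterexample: Trajectory | None = None
    #: index into the counterexample where a violating loop starts, if any
    loop_start: int | None = None

    @property
    def passed(self) -> bool:
        return self.status == "pass"


def _level_at_least(model: NetworkModel, node: str, level: int):
    idx = model.index[node]
    if not 0 < level <= model.nodes[idx].max_level:
        raise ValueError(f"level {level} out of range for node {node!r}")
    return lambda s: s[idx] >= level


def _resolve_obligation(model: NetworkModel, obligation):
    if isinstance(obligation, str):
        target = model.reference_states[obligation]
        return lambda s: s == target
    node, level = obligation
    return _level_at_least(model, node, level)


def _trace(parents, end: State) -> list[State]:
    out = [end]
    while parents[out[-1]] is not None:
        out.append(parents[out[-1]])
    out.reverse()
    return out


def _updates_along(model: NetworkModel, states: Sequence[State]) -> list[str]:
    names = []
    for a, b in zip(states, states[1:]):
        diff = [
            model.node_names[i]
            for i in range(len(a.levels))
            if a[i] != b[i]
        ]
        assert len(diff) == 1, "asynchronous steps change exactly one node"
        names.append(diff[0])
    return names


def _as_trajectory(model: NetworkModel, states: list[State]) -> Trajectory:
    return Trajectory(
        states=states,
        mode="async",
        update_sequence=_updates_along(model, states),
    )


def check_precedence(
    model: NetworkModel,
    initial: State,
    prop: PrecedenceProperty,
    max_states: int = DEFAULT_STATE_CAP,
) -> PropertyVerdict:
    """Monitor-augmented BFS for ordering violations; shortest witness on failure.

    The search space is the asynchronous state graph crossed with one bit
    recording whether the antecedent has been satisfied so far.  A
    violation is a reachable configuration whose state satisfies the
    consequent while the bit is still clear.  BFS guarantees the returned
    counterexample is a shortest one.
    """
    ant = _level_at_least(model, *prop.antecedent)
    cons = _level_at_least(model, *prop.consequent)

    start = (initial, ant(initial))
    parents: dict[tuple[State, bool], tuple[State, bool] | None] = {start: None}
    frontier = [start]
    while frontier:
        nxt_frontier = []
        for cfg in frontier:
            state, seen = cfg
            if cons(state) and not seen:
                # rebuild the state path from parent pointers
                path = [cfg]
                while parents[path[-1]] is not None:
                    path.append(parents[path[-1]])
                path.reverse()
                return PropertyVerdict(
                    prop.name, prop.group, "fail",
                    _as_trajectory(model, [c[0] for c in path]),
                )
            for _, succ in async_successors(model, state):
                nxt_cfg = (succ, seen or ant(succ))
                if nxt_cfg not in parents:
                    if len(parents) >= 2 * max_states:
                        raise RuntimeError("state cap exceeded in precedence check")
                    parents[nxt_cfg] = cfg
                    nxt_frontier.append(nxt_cfg)
        frontier = nxt_frontier
    return PropertyVerdict(prop.name, prop.group, "pass")


def _fair_sustainable(model: NetworkModel, comp: set[State]) -> bool:
    """Whether a fair run can remain inside the component forever.

    Every node must either have a no-op update at some component state or
    an update edge that stays inside the component; otherwise scheduling
    that node (which fairness forces infinitely often) ejects the run.
    """
    comp_set = set(comp)
    for i, name in enumerate(model.node_names):
        ok = False
        for s in comp_set:
            t = local_target(model, s, name)
            if t == s[i]:
                ok = True
                break
            step = 1 if t > s[i] else -1
            succ = State(s.levels[:i] + (s[i] + step,) + s.levels[i + 1:])
            if succ in comp_set:
                ok = True
                break
        if not ok:
            return False
    return True


def _fair_avoidance_witness(
    model: NetworkModel, g: nx.DiGraph, start: State, bad: set[State]
):
    """A fair run from ``start`` that avoids ``bad`` forever, if one exists.

    Such a run is either a path to a state with no successors (an
    absorbing state outside ``bad``) or a path into a fair-sustainable
    SCC disjoint from ``bad``.  Returns ``(path, loop_start)`` or
    ``None``; the search stays inside the subgraph avoiding ``bad``.
    """
    if start in bad:
        return None
    sub_nodes = [n for n in g.nodes if n not in bad]
    h = g.subgraph(sub_nodes)
    reach = {start} | set(nx.descendants(h, start))
    # absorbing in the full graph = no value-changing successor at all
    for s in sorted(reach, key=lambda s: s.levels):
        if g.out_degree(s) == 0:
            path = nx.shortest_path(h, start, s)
            return list(path), None
    hr = h.subgraph(reach)
    comps = [c for c in nx.strongly_connected_components(hr) if len(c) > 1]
    comps.sort(key=lambda c: min(s.levels for s in c))
    for comp in comps:
        if not _fair_sustainable(model, comp):
            continue
        anchor = min(comp, key=lambda s: s.levels)
        path = list(nx.shortest_path(h, start, anchor))
        nxt = next(t for t in hr.successors(anchor) if t in comp)
        cycle = [nxt]
        while cycle[-1] != anchor:
            cycle.append(nx.shortest_path(hr.subgraph(comp), cycle[-1], anchor)[1])
        return path + cycle, len(path) - 1
    return None


def check_response(
    model: NetworkModel,
    initial: State,
    prop: ResponseProperty,
    max_states: int = DEFAULT_STATE_CAP,
) -> PropertyVerdict:
    """Fails iff some fair path from a reachable trigger state avoids the obligation."""
    trig = _level_at_least(model, *prop.trigger)
    oblig = _resolve_obligation(model, prop.obligation)

    tg = reachable_graph(model, initial, "async", max_states)
    g = tg.graph
    bad = {s for s in g.nodes if oblig(s)}
    trigger_states = sorted((s for s in g.nodes if trig(s)), key=lambda s: s.levels)
    for t in trigger_states:
        witness = _fair_avoidance_witness(model, g, t, bad)
        if witness is not None:
            suffix, loop_rel = witness
            prefix = list(nx.shortest_path(g, initial, t))
            states = prefix[:-1] + suffix
            loop = None if loop_rel is None else len(prefix) - 1 + loop_rel
            return PropertyVerdict(
                prop.name, prop.group, "fail",
                _as_trajectory(model, states), loop_start=loop,
            )
    return PropertyVerdict(prop.name, prop.group, "pass")


def check_global_attractor(
    model: NetworkModel,
    initial: State,
    target: State,
    name: str = "global_attractor",
    group: str = "global",
    max_states: int = DEFAULT_STATE_CAP,
) -> PropertyVerdict:
    """Every fair asynchronous run from ``initial`` must end at ``target``.

    Passes iff the reachable graph has exactly one terminal SCC, equal to
    ``{target}``, and no other cycle among reachable states.  The failure
    witness is a path to a wrong absorbing state or a lasso into a cycle.
    """
    if not is_fixed_point(model, target):
        raise ValueError("global-attractor target must be a fixed point")
    tg = reachable_graph(model, initial, "async", max_states)
    witness = _fair_avoidance_witness(model, tg.graph, initial, {target})
    if witness is None:
        return PropertyVerdict(name, group, "pass")
    states, loop = witness
    return PropertyVerdict(
        name, group, "fail", _as_trajectory(model, states), loop_start=loop
    )


def check_property(
    model: NetworkModel,
    initial: State,
    prop: Property,
    max_states: int = DEFAULT_STATE_CAP,
) -> PropertyVerdict:
    if isinstance(prop, PrecedenceProperty):
        return check_precedence(model, initial, prop, max_states)
    if isinstance(prop, ResponseProperty):
        return check_response(model, initial, prop, max_states)
    if isinstance(prop, GlobalAttractorProperty):
        return check_global_attractor(
            model, initial, model.reference_states[prop.target],
            name=prop.name, group=prop.group, max_states=max_states,
        )
    raise TypeError(f"unknown property type {type(prop)!r}")


def check_all(
    model: NetworkModel,
    initial: State | None = None,
    properties: Sequence[Property] | None = None,
    max_states: int = DEFAULT_STATE_CAP,
) -> list[PropertyVerdict]:
    if initial is None:
        initial = model.stimulated_g1
    if properties is None:
        properties = default_property_set(model)
    return [check_property(model, initial, p, max_states) for p in properties]


# ---------------------------------------------------------------------------
# property sets (data, not code)
# ---------------------------------------------------------------------------

def _parse_property(rec: dict, model: NetworkModel) -> Property:
    kind = rec["type"]
    name = rec["name"]
    group = rec.get("group", "")

    def pair(obj, top_level_ok=True):
        node = obj["node"]
        level = obj.get("level", 1)
        if level == "max":
            level = model.nodes[model.index[node]].max_level
        return (node, int(level))

    if kind == "precedence":
        return PrecedenceProperty(pair(rec["antecedent"]), pair(rec["consequent"]), name, group)
    if kind == "response":
        ob = rec["obligation"]
        obligation = ob["state"] if "state" in ob else pair(ob)
        return ResponseProperty(pair(rec["trigger"]), obligation, name, group)
    if kind == "global_attractor":
        return GlobalAttractorProperty(rec.get("target", "stationary_g1"), name, group)
    raise ValueError(f"unknown property type {kind!r}")


def load_property_set(path_or_records, model: NetworkModel) -> list[Property]:
    """Instantiate a property list from a JSON file path or parsed records."""
    if isinstance(path_or_records, (str, bytes)) or hasattr(path_or_records, "read_text"):
        records = json.loads(
            path_or_records.read_text()
            if hasattr(path_or_records, "read_text")
            else open(path_or_records).read()
        )
    else:
        records = path_or_records
    return [_parse_property(rec, model) for rec in records]


def default_property_set(model: NetworkModel) -> list[Property]:
    """The bundled checkpoint property set, instantiated for ``model``.

    Levels written as ``"max"`` in the config resolve against the model, so
    "Swi5 fully active" means level 1 for a binary Swi5 and level 2 for a
    ternary one.
    """
    missing = set(CANONICAL_NODES) - set(model.node_names)
    if missing:
        raise ValueError(f"model lacks canonical nodes {sorted(missing)}")
    text = resources.files("budcycle.config").joinpath("default_properties.json").read_text()
    return load_property_set(json.loads(text), model)


# ---------------------------------------------------------------------------
# SMV export
# ---------------------------------------------------------------------------

def _sum_expr(model: NetworkModel, node: str) -> str:
    """The node's weighted input sum, scaled by 6 to keep SMV arithmetic integral."""
    terms = []
    for e in model.edges:
        if e.target != node:
            continue
        w6 = int(e.weight * 6)
        terms.append(f"({w6} * {e.source})")
    return " + ".join(terms) if terms else "0"


def _cond_expr(model: NetworkModel, cond: tuple[str, int]) -> str:
    node, level = cond
    return f"{node} >= {level}"


def export_nusmv(
    model: NetworkModel,
    initial: State | None = None,
    properties: Sequence[Property] | None = None,
) -> str:
    """Emit the model, fairness constraints and CTL specs in NuSMV syntax.

    The asynchronous schedule is encoded with a control variable ``turn``
    choosing which node's update rule fires; one FAIRNESS constraint per
    node keeps every node scheduled infinitely often.  Precedence
    properties compile to a safety formula over a monitor variable;
    response and attractor properties to fair AF formulas.
    """
    if initial is None:
        initial = model.stimulated_g1
    if properties is None:
        properties = default_property_set(model)
    L: list[str] = ["MODULE main", "VAR"]
    L.append("  turn : {" + ", ".join(model.node_names) + "};")
    for n in model.nodes:
        L.append(f"  {n.name} : 0..{n.max_level};")
    monitors = [p for p in properties if isinstance(p, PrecedenceProperty)]
    for i, p in enumerate(monitors):
        L.append(f"  seen_{i} : boolean;")
    L.append("DEFINE")
    for n in model.nodes:
        L.append(f"  sum_{n.name} := {_sum_expr(model, n.name)};")
    L.append("ASSIGN")
    for n, v in zip(model.nodes, initial.levels):
        L.append(f"  init({n.name}) := {v};")
    for n in model.nodes:
        nm = n.name
        if model.semantics == "li_binary":
            decay = f"{nm} > 0 ? 0 : {nm}" if n.self_degrading else nm
            update = (
                f"    turn = {nm} & sum_{nm} > 0 : 1;\n"
                f"    turn = {nm} & sum_{nm} < 0 : 0;\n"
                f"    turn = {nm} : {decay};"
            )
        else:
            clauses = []
            for s in range(n.max_level):
                th6 = int(n.thresholds[s] * 6)
                clauses.append(
                    f"    turn = {nm} & {nm} = {s} & sum_{nm} >= {th6} : {s + 1};"
                )
            for s in range(1, n.max_level + 1):
                th6 = int(n.thresholds[s - 1] * 6)
                clauses.append(
                    f"    turn = {nm} & {nm} = {s} & sum_{nm} < {th6} : {s - 1};"
                )
            update = "\n".join(clauses)
        L.append(f"  next({nm}) :=\n   case\n{update}\n    TRUE : {nm};\n   esac;")
    for i, p in enumerate(monitors):
        ant = _cond_expr(model, p.antecedent)
        L.append(f"  init(seen_{i}) := {ant};")
        nxt_ant = ant.replace(p.antecedent[0], f"next({p.antecedent[0]})", 1)
        L.append(f"  next(seen_{i}) := seen_{i} | ({nxt_ant});")
    for nm in model.node_names:
        L.append(f"FAIRNESS turn = {nm}")
    for i, p in enumerate(monitors):
        cons = _cond_expr(model, p.consequent)
        L.append(f"-- {p.name}")
        L.append(f"SPEC AG (({cons}) -> seen_{i})")
    for p in properties:
        if isinstance(p, ResponseProperty):
            trig = _cond_expr(model, p.trigger)
            if isinstance(p.obligation, str):
                target = model.reference_states[p.obligation]
                ob = " & ".join(
                    f"{n} = {v}" for n, v in zip(model.node_names, target.levels)
                )
            else:
                ob = _cond_expr(model, p.obligation)
            L.append(f"-- {p.name}")
            L.append(f"SPEC AG (({trig}) -> AF ({ob}))")
        elif isinstance(p, GlobalAttractorProperty):
            target = model.reference_states[p.target]
            ob = " & ".join(
                f"{n} = {v}" for n, v in zip(model.node_names, target.levels)
            )
            L.append(f"-- {p.name}")
            L.append(f"SPEC AF ({ob})")
    return "\n".join(L) + "\n"
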