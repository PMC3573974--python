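"""Update rules and synchronous/asynchronous stepping.

All arithmetic is exact: weighted input sums are computed on weights scaled
by 6 (so the multilevel alphabet {±1/3, ±1, ±3} becomes {±2, ±6, ±18} and
the thresholds 1/2, 3/2 become 3, 9), which keeps every comparison in
integers.  Because scaled sums are even and scaled thresholds odd, the
rule's >= / < comparisons can never land on a tie in the multilevel
semantics; in the Li semantics the tie at 0 is meaningful and handled
explicitly.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterator, Sequence

from .netdef import NetworkModel, State

__all__ = [
    "Trajectory",
    "compiled",
    "local_target",
    "sync_step",
    "async_successors",
    "is_fixed_point",
    "simulate",
    "trajectory_to_tsv",
]

_SCALE = 6


class _Compiled:
    """Integer-scaled update tables for one model (cached on the model)."""

    __slots__ = ("weights", "thresholds", "max_levels", "li_tie_decay", "semantics")

    def __init__(self, model: NetworkModel) -> None:
        n = len(model.nodes)
        self.semantics = model.semantics
        self.max_levels = model.max_levels
        # weights[i] = list of (source index, scaled weight)
        self.weights: list[list[tuple[int, int]]] = [[] for _ in range(n)]
        for e in model.edges:
            w6 = e.weight * _SCALE
            assert w6.denominator == 1
            self.weights[model.index[e.target]].append((model.index[e.source], int(w6)))
        # thresholds[i][s] = scaled entry threshold of level s+1
        self.thresholds = [
            [int(t * _SCALE) for t in node.thresholds] for node in model.nodes
        ]
        self.li_tie_decay = [node.self_degrading for node in model.nodes]

    def target(self, levels: Sequence[int], i: int) -> int:
        sigma = 0
        for j, w in self.weights[i]:
            sigma += w * levels[j]
        s = levels[i]
        if self.semantics == "li_binary":
            theta = self.thresholds[i][0]
            if sigma > theta:
                return 1
            if sigma < theta:
                return 0
            if self.li_tie_decay[i] and s > 0:
                return 0
            return s
        # multilevel, rise: one level when the next entry threshold is met
        if s < self.max_levels[i] and sigma >= self.thresholds[i][s]:
            return s + 1
        if s > 0:
            if self.max_levels[i] == 1:
                # binary nodes keep the Li tie semantics: a neutral band of
                # width one below the entry threshold retains the level,
                # decaying only for flagged nodes; below the band the node
                # switches off
                theta = self.thresholds[i][0]
                if sigma <= theta - _SCALE:
                    return 0
                if sigma < theta and self.li_tie_decay[i]:
                    return 0
                return s
            # graded nodes require sustained input at every level
            if sigma < self.thresholds[i][s - 1]:
                return s - 1
        return s


def compiled(model: NetworkModel) -> _Compiled:
    comp = getattr(model, "_compiled", None)
    if comp is None:
        comp = _Compiled(model)
        model._compiled = comp  # type: ignore[attr-defined]
    return comp


def local_target(model: NetworkModel, state: State, node: str) -> int:
    """The level ``node`` would take at the next instant from ``state``."""
    if node not in model.index:
        raise KeyError(f"unknown node {node!r}")
    return compiled(model).target(state.levels, model.index[node])


def sync_step(model: NetworkModel, state: State) -> State:
    """Apply the update rule to every node against the same predecessor."""
    comp = compiled(model)
    levels = state.levels
    return State(tuple(comp.target(levels, i) for i in range(len(levels))))


def async_successors(model: NetworkModel, state: State) -> list[tuple[str, State]]:
    """Value-changing single-node updates, in canonical node order.

    One entry per node whose local target differs from its current level;
    no-op updates are omitted (they only stutter the schedule).
    """
    comp = compiled(model)
    levels = state.levels
    out: list[tuple[str, State]] = []
    for i, name in enumerate(model.node_names):
        t = comp.target(levels, i)
        if t != levels[i]:
            succ = levels[:i] + (t,) + levels[i + 1:]
            out.append((name, State(succ)))
    return out


def is_fixed_point(model: NetworkModel, state: State) -> bool:
    return sync_step(model, state) == state


@dataclass
class Trajectory:
    """An ordered run of states under one update mode.

    ``update_sequence`` names the node updated at each asynchronous step;
    it is empty for synchronous runs.  ``hit_step_cap`` flags a run stopped
    by ``max_steps`` rather than by reaching a fixed point.
    """

    states: list[State]
    mode: str
    scheduler_seed: int | None = None
    update_sequence: list[str] = field(default_factory=list)
    hit_step_cap: bool = False

    def __len__(self) -> int:
        return len(self.states)

    @property
    def n_steps(self) -> int:
        return len(self.states) - 1

    def levels_of(self, model: NetworkModel, node: str) -> list[int]:
        i = model.index[node]
        return [s[i] for s in self.states]

    def first_time_at(self, model: NetworkModel, node: str, level: int) -> int | None:
        """Index of the first state where ``node`` is at ``level`` or above."""
        i = model.index[node]
        for t, s in enumerate(self.states):
            if s[i] >= level:
                return t
        return None


def simulate(
    model: NetworkModel,
    start: State,
    mode: str = "sync",
    max_steps: int = 1000,
    seed: int | None = None,
) -> Trajectory:
    """Run the model forward until a fixed point or ``max_steps``.

    Synchronous runs are deterministic.  Asynchronous runs pick uniformly
    among the enabled (value-changing) nodes using ``seed``; the same seed
    reproduces the same trajectory.
    """
    if max_steps <= 0:
        raise ValueError("max_steps must be positive")
    if mode not in ("sync", "async"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = random.Random(seed)
    states = [start]
    updates: list[str] = []
    capped = False
    current = start
    for _ in range(max_steps):
        if mode == "sync":
            nxt = sync_step(model, current)
            if nxt == current:
                break
            states.append(nxt)
            current = nxt
        else:
            succs = async_successors(model, current)
            if not succs:
                break
            name, nxt = rng.choice(succs)
            states.append(nxt)
            updates.append(name)
            current = nxt
    else:
        capped = bool(async_successors(model, current)) if mode == "async" else (
            sync_step(model, current) != current
        )
    return Trajectory(
        states=states,
        mode=mode,
        scheduler_seed=seed,
        update_sequence=updates,
        hit_step_cap=capped,
    )


def trajectory_to_tsv(model: NetworkModel, traj: Trajectory) -> str:
    """One row per step, columns in canonical node order (plus updated_node)."""
    header = ["step", *model.node_names]
    if traj.mode == "async":
        header.append("updated_node")
    lines = ["\t".join(header)]
    for t, s in enumerate(traj.states):
        row = [str(t), *map(str, s.levels)]
        if traj.mode == "async":
            row.append(traj.update_sequence[t - 1] if t > 0 else "-")
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
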