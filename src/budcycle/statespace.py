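"""Explicit transition graphs, fixed points, synchronous basins, terminal SCCs.

The state spaces here are small (at most 4,608 states for the bundled
models), so everything is exact and explicit: attractor basins are found by
iterating the synchronous map over the *entire* state space, and the
asynchronous reachable graph is built by breadth-first closure.  Symbolic
(BDD) representations are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .dynamics import async_successors, sync_step
from .netdef import NetworkModel, State

__all__ = [
    "StateCapExceeded",
    "TransitionGraph",
    "Attractor",
    "reachable_graph",
    "synchronous_attractors",
    "terminal_sccs",
    "attractor_table",
    "graph_to_tsv",
]

DEFAULT_STATE_CAP = 10**6


class StateCapExceeded(RuntimeError):
    """Raised when an exploration would exceed the configured state cap."""


@dataclass
class TransitionGraph:
    """Explicit directed graph over states reachable from ``initial``.

    ``graph`` is a :class:`networkx.DiGraph` whose nodes are :class:`State`
    objects; each edge carries the updated node's name in attribute
    ``node`` (synchronous edges use ``"*"``).
    """

    graph: nx.DiGraph
    initial: State
    mode: str

    @property
    def states(self) -> set[State]:
        return set(self.graph.nodes)

    def n_states(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def reachable_graph(
    model: NetworkModel,
    initial: State,
    mode: str = "async",
    max_states: int = DEFAULT_STATE_CAP,
) -> TransitionGraph:
    """Breadth-first closure of the update relation from ``initial``.

    Exploration order is deterministic: the frontier is a FIFO queue and
    successors are generated in canonical node order.
    """
    if mode not in ("sync", "async"):
        raise ValueError(f"unknown mode {mode!r}")
    g = nx.DiGraph()
    g.add_node(initial)
    frontier = [initial]
    seen = {initial}
    while frontier:
        state = frontier.pop(0)
        if mode == "sync":
            nxt = sync_step(model, state)
            succs = [] if nxt == state else [("*", nxt)]
        else:
            succs = async_successors(model, state)
        for node_name, succ in succs:
            if succ not in seen:
                if len(seen) >= max_states:
                    raise StateCapExceeded(
                        f"reachable set exceeds cap of {max_states} states"
                    )
                seen.add(succ)
                frontier.append(succ)
            g.add_edge(state, succ, node=node_name)
    return TransitionGraph(graph=g, initial=initial, mode=mode)


@dataclass
class Attractor:
    """A terminal fixed point or cycle with its synchronous basin size."""

    kind: str  # "fixed_point" | "cycle"
    states: tuple[State, ...]
    basin_size: int

    @property
    def state(self) -> State:
        if self.kind != "fixed_point":
            raise ValueError("cycle attractor has no single state")
        return self.states[0]


def _full_space_array(model: NetworkModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All states as an (N, n) level array plus mixed-radix encoders."""
    radix = np.array([n.max_level + 1 for n in model.nodes], dtype=np.int64)
    mult = np.cumprod(np.concatenate([[1], radix[:-1]])).astype(np.int64)
    total = int(np.prod(radix))
    codes = np.arange(total, dtype=np.int64)
    levels = np.empty((total, len(radix)), dtype=np.int64)
    rem = codes.copy()
    for i, r in enumerate(radix):
        levels[:, i] = rem % r
        rem //= r
    return levels, mult, radix


def _sync_map(model: NetworkModel, levels: np.ndarray) -> np.ndarray:
    """Vectorized one-step synchronous image of every row of ``levels``."""
    n = len(model.nodes)
    weights = np.zeros((n, n), dtype=np.int64)  # scaled by 6
    for e in model.edges:
        w6 = e.weight * 6
        weights[model.index[e.target], model.index[e.source]] = int(w6)
    maxlev = np.array(model.max_levels, dtype=np.int64)
    sigma = levels @ weights.T
    if model.semantics == "li_binary":
        decay = np.array([n_.self_degrading for n_ in model.nodes])
        tie = np.where(decay & (levels > 0), 0, levels)
        return np.where(sigma > 0, 1, np.where(sigma < 0, 0, tie))
    # entry threshold of level s is 6*s - 3 (i.e. s - 1/2, scaled by 6)
    up = (levels < maxlev) & (sigma >= 6 * (levels + 1) - 3)
    decay = np.array([n_.self_degrading for n_ in model.nodes])
    binary = maxlev == 1
    down_binary = binary & (levels > 0) & (
        (sigma <= -3) | ((sigma < 3) & decay)
    )
    down_graded = ~binary & (levels > 0) & (sigma < 6 * levels - 3)
    down = down_binary | down_graded
    return levels + up.astype(np.int64) - down.astype(np.int64)


def synchronous_attractors(
    model: NetworkModel, max_states: int = DEFAULT_STATE_CAP
) -> list[Attractor]:
    """Exact attractors and basin sizes over the full synchronous state space.

    Every state is iterated under the synchronous map; the terminal fixed
    point or limit cycle is identified by pointer doubling (for fixed
    points) with an explicit cycle resolution pass.  Attractors are sorted
    by descending basin size, then canonical state order.
    """
    total = model.state_space_size()
    if total > max_states:
        raise StateCapExceeded(f"state space of {total} exceeds cap {max_states}")
    levels, mult, _ = _full_space_array(model)
    step_codes = (_sync_map(model, levels) * mult).sum(axis=1)

    f = step_codes.copy()
    for _ in range(64):  # 2**64 far exceeds any transient length
        f2 = f[f]
        if np.array_equal(f2, f):
            break
        f = f2
    fixed_mask = step_codes == np.arange(total)

    basins: dict[tuple[int, ...], int] = {}
    cycle_of: dict[int, tuple[int, ...]] = {}
    for code in range(total):
        dest = int(f[code])
        if fixed_mask[dest]:
            key = (dest,)
        else:
            # state feeds a limit cycle: walk it once, canonicalize
            if dest not in cycle_of:
                cyc = [dest]
                cur = int(step_codes[dest])
                while cur != dest:
                    cyc.append(cur)
                    cur = int(step_codes[cur])
                start = cyc.index(min(cyc))
                key = tuple(cyc[start:] + cyc[:start])
                for c in cyc:
                    cycle_of[c] = key
            key = cycle_of[dest]
        basins[key] = basins.get(key, 0) + 1

    def decode(code: int) -> State:
        vec = []
        for node in model.nodes:
            r = node.max_level + 1
            vec.append(code % r)
            code //= r
        return State(tuple(vec))

    attractors = [
        Attractor(
            kind="fixed_point" if len(key) == 1 else "cycle",
            states=tuple(decode(c) for c in key),
            basin_size=count,
        )
        for key, count in basins.items()
    ]
    attractors.sort(key=lambda a: (-a.basin_size, a.states))
    return attractors


def terminal_sccs(tg: TransitionGraph) -> list[set[State]]:
    """Strongly connected components with no outgoing edges, in canonical order."""
    cond = nx.condensation(tg.graph)
    out = []
    for comp_id in cond.nodes:
        if cond.out_degree(comp_id) == 0:
            out.append(set(cond.nodes[comp_id]["members"]))
    out.sort(key=lambda comp: min(s.levels for s in comp))
    return out


def attractor_table(model: NetworkModel, attractors: list[Attractor]) -> str:
    """TSV report mirroring the printed attractor tables (basin + node columns)."""
    lines = ["\t".join(["basin_size", *model.node_names])]
    for a in attractors:
        if a.kind == "fixed_point":
            lines.append("\t".join([str(a.basin_size), *map(str, a.state.levels)]))
        else:
            for i, s in enumerate(a.states):
                tag = f"{a.basin_size} (cycle)" if i == 0 else ""
                lines.append("\t".join([tag, *map(str, s.levels)]))
    return "\n".join(lines) + "\n"


def graph_to_tsv(tg: TransitionGraph) -> str:
    """Edge list ``src<TAB>node<TAB>dst`` with states as level strings."""
    rows = sorted(
        (src.levels, data["node"], dst.levels)
        for src, dst, data in tg.graph.edges(data=True)
    )
    lines = ["src\tnode\tdst"]
    for src, node, dst in rows:
        lines.append(
            "{}\t{}\t{}".format(
                "".join(map(str, src)), node, "".join(map(str, dst))
            )
        )
    return "\n".join(lines) + "\n"
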