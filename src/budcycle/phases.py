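"""Phase segmentation of trajectories and per-phase path statistics.

A :class:`PhaseConfig` is an ordered list of phase markers.  The first
phase starts at the cycle-start state (the stimulated G1 state); each
later phase begins when its entry condition first becomes true, and once
entered a phase never reverts (labels are latched).  The cycle ends on
arrival at the stationary G1 state.

Two configurations ship as data:

* the 2-segment split (S, then G2/M at Clb2 >= 1) used for phase-duration
  statistics, and
* the 4-segment split (G1, S at Clb5 >= 1, G2 at Clb2 >= 1, M at
  Cdc20 >= 1) used for per-phase transition counts.

Duration statistics enumerate *all distinct simple paths* from the
stimulated G1 state to the stationary G1 state in the asynchronous
transition graph, each path weighted equally; a seeded scheduler-weighted
sampling mode is available as an alternative.  Variances are population
variances by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx
import numpy as np

from .dynamics import Trajectory, simulate
from .netdef import NetworkModel, State
from .statespace import DEFAULT_STATE_CAP, TransitionGraph, reachable_graph

__all__ = [
    "PhaseMarker",
    "PhaseConfig",
    "PhaseStats",
    "two_phase_config",
    "four_phase_config",
    "label_trajectory",
    "enumerate_cycle_paths",
    "phase_length_stats",
    "sample_phase_lengths",
    "phase_transition_counts",
    "stats_to_tsv",
    "counts_to_tsv",
    "PathCapExceeded",
]

DEFAULT_PATH_CAP = 5_000_000


class PathCapExceeded(RuntimeError):
    """Raised when simple-path enumeration would exceed the configured cap."""


@dataclass(frozen=True)
class PhaseMarker:
    """Entry condition of one phase: ``node`` reaching ``level`` (or cycle start)."""

    name: str
    node: str | None = None  # None = cycle start
    level: int = 1

    def entered(self, model: NetworkModel, state: State) -> bool:
        if self.node is None:
            return True
        return state[model.index[self.node]] >= self.level


@dataclass(frozen=True)
class PhaseConfig:
    """Ordered phase markers; the first marker must be the cycle start."""

    markers: tuple[PhaseMarker, ...]

    def __post_init__(self) -> None:
        if not self.markers or self.markers[0].node is not None:
            raise ValueError("first phase must start at the cycle-start state")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.markers)


def two_phase_config() -> PhaseConfig:
    return PhaseConfig(
        (PhaseMarker("S"), PhaseMarker("G2/M", "Clb2", 1))
    )


def four_phase_config() -> PhaseConfig:
    return PhaseConfig(
        (
            PhaseMarker("G1"),
            PhaseMarker("S", "Clb5", 1),
            PhaseMarker("G2", "Clb2", 1),
            PhaseMarker("M", "Cdc20", 1),
        )
    )


def label_trajectory(
    model: NetworkModel, traj: Trajectory, config: PhaseConfig
) -> list[str]:
    """Latched phase label per trajectory position, up to the cycle end.

    The label of a position is the latest marker satisfied at or before
    it.  Labelling stops at the stationary G1 state (exclusive): a
    trajectory already at rest yields an empty labelling.
    """
    end = model.stationary_g1
    labels: list[str] = []
    current = 0
    for state in traj.states:
        if state == end:
            break
        while (
            current + 1 < len(config.markers)
            and config.markers[current + 1].entered(model, state)
        ):
            current += 1
        labels.append(config.markers[current].name)
    return labels


def _phase_index_fn(
    model: NetworkModel, config: PhaseConfig
) -> Callable[[State, int], int]:
    """Latched phase index given a state and the previously latched index."""

    def fn(state: State, latched: int) -> int:
        while (
            latched + 1 < len(config.markers)
            and config.markers[latched + 1].entered(model, state)
        ):
            latched += 1
        return latched

    return fn


def enumerate_cycle_paths(
    model: NetworkModel,
    max_states: int = DEFAULT_STATE_CAP,
    path_cap: int = DEFAULT_PATH_CAP,
) -> tuple[nx.DiGraph, State, State, bool]:
    """The async reachable graph pruned to states that can reach stationary G1.

    Returns ``(graph, start, end, is_dag)``.  When the pruned graph is
    acyclic every path is simple and statistics can be computed by exact
    dynamic programming; otherwise enumeration is restricted to simple
    paths (reported by the caller).
    """
    start = model.stimulated_g1
    end = model.stationary_g1
    tg = reachable_graph(model, start, "async", max_states)
    if end not in tg.graph:
        raise ValueError("stationary G1 is not reachable from stimulated G1")
    keep = nx.ancestors(tg.graph, end) | {end}
    if start not in keep:
        raise ValueError("no path from stimulated G1 reaches stationary G1")
    h = tg.graph.subgraph(keep).copy()
    return h, start, end, nx.is_directed_acyclic_graph(h)


@dataclass
class PhaseStats:
    """Per-phase mean/variance of segment lengths and distinct-edge counts."""

    phases: tuple[str, ...]
    n_paths: int
    mean: dict[str, float] = field(default_factory=dict)
    variance: dict[str, float] = field(default_factory=dict)
    transition_counts: dict[str, int] = field(default_factory=dict)
    simple_paths_only: bool = False  # True when cycles forced the restriction
    sampled: bool = False


def _dp_segment_stats(
    h: nx.DiGraph,
    start: State,
    end: State,
    phase_of: Callable[[State, int], int],
    n_phases: int,
    start_phase: int,
) -> tuple[int, np.ndarray, np.ndarray, np.ndarray]:
    """Exact equal-weight path statistics on a DAG without enumeration.

    For each (state, latched phase) node of the product DAG we accumulate,
    over all partial paths from the start: the path count, the per-phase
    sums of segment lengths, their squares and pairwise products — enough
    to recover exact means and population (co)variances at the end state.
    Arithmetic is exact (Python integers via object arrays).
    """
    order = list(nx.topological_sort(h))
    k = n_phases
    # accumulators per (state, phase): count, sums[k], sumsq[k, k]
    acc: dict[tuple[State, int], list] = {}

    def zero():
        return [0, np.zeros(k, dtype=object), np.zeros((k, k), dtype=object)]

    first = acc[(start, start_phase)] = zero()
    first[0] = 1
    for v in order:
        for p in range(k):
            cell = acc.get((v, p))
            if cell is None or cell[0] == 0:
                continue
            cnt, sums, sumsq = cell
            if v == end:
                continue
            for w in h.successors(v):
                q = phase_of(w, p)
                # the transition v->w belongs to the phase latched at v
                tgt = acc.setdefault((w, q), zero())
                tgt[0] += cnt
                d = np.zeros(k, dtype=object)
                d[p] = 1
                tgt[1] += sums + cnt * d
                tgt[2] += sumsq + np.outer(d, sums) + np.outer(sums, d) + cnt * np.outer(d, d)
    total = zero()
    for p in range(k):
        cell = acc.get((end, p))
        if cell is None:
            continue
        total[0] += cell[0]
        total[1] = total[1] + cell[1]
        total[2] = total[2] + cell[2]
    return total[0], total[1], total[2], None


def phase_length_stats(
    model: NetworkModel,
    config: PhaseConfig | None = None,
    max_states: int = DEFAULT_STATE_CAP,
    path_cap: int = DEFAULT_PATH_CAP,
    ddof: int = 0,
) -> PhaseStats:
    """Mean and variance of per-phase segment lengths over all cycle paths.

    Every distinct path from stimulated G1 to stationary G1 in the
    asynchronous transition graph carries equal weight.  Lengths count
    value-changing updates; a path's segment for phase P is the number of
    its transitions leaving a state labelled P.  On an acyclic graph the
    computation is exact DP; otherwise simple paths are enumerated up to
    ``path_cap``.
    """
    if config is None:
        config = two_phase_config()
    h, start, end, is_dag = enumerate_cycle_paths(model, max_states, path_cap)
    phase_of = _phase_index_fn(model, config)
    k = len(config.markers)
    start_phase = phase_of(start, 0)

    if is_dag:
        n_paths, sums, sumsq, _ = _dp_segment_stats(
            h, start, end, phase_of, k, start_phase
        )
        simple_only = False
    else:
        n_paths = 0
        sums = np.zeros(k, dtype=object)
        sumsq = np.zeros((k, k), dtype=object)
        seg = np.zeros(k, dtype=object)

        def dfs(v: State, latched: int, visited: set[State]):
            nonlocal n_paths, sums, sumsq
            if v == end:
                n_paths += 1
                if n_paths > path_cap:
                    raise PathCapExceeded(
                        f"more than {path_cap} simple paths; use sampling mode"
                    )
                sums += seg
                sumsq += np.outer(seg, seg)
                return
            for w in h.successors(v):
                if w in visited:
                    continue
                q = phase_of(w, latched)
                seg[latched] += 1
                visited.add(w)
                dfs(w, q, visited)
                visited.remove(w)
                seg[latched] -= 1

        dfs(start, start_phase, {start})
        simple_only = True

    stats = PhaseStats(
        phases=config.names, n_paths=int(n_paths), simple_paths_only=simple_only
    )
    denom = n_paths - ddof
    for i, name in enumerate(config.names):
        mean = sums[i] / n_paths
        var = (sumsq[i, i] - n_paths * mean * mean) / denom
        stats.mean[name] = float(mean)
        stats.variance[name] = float(var)
    return stats


def sample_phase_lengths(
    model: NetworkModel,
    config: PhaseConfig | None = None,
    n_runs: int = 10_000,
    seed: int = 0,
    max_steps: int = 10_000,
) -> PhaseStats:
    """Scheduler-weighted alternative: seeded uniform-async runs.

    Runs that do not terminate at stationary G1 (other attractors, step
    cap) are discarded; reported statistics are over completing runs.
    """
    if config is None:
        config = two_phase_config()
    end = model.stationary_g1
    k = len(config.markers)
    phase_of = _phase_index_fn(model, config)
    segs = []
    for r in range(n_runs):
        traj = simulate(model, model.stimulated_g1, "async", max_steps, seed * n_runs + r)
        if traj.states[-1] != end:
            continue
        seg = [0] * k
        latched = phase_of(traj.states[0], 0)
        for state in traj.states[1:]:
            seg[latched] += 1
            latched = phase_of(state, latched)
        segs.append(seg)
    arr = np.array(segs, dtype=float)
    stats = PhaseStats(phases=config.names, n_paths=len(segs), sampled=True)
    for i, name in enumerate(config.names):
        stats.mean[name] = float(arr[:, i].mean())
        stats.variance[name] = float(arr[:, i].var())
    return stats


def phase_transition_counts(
    model: NetworkModel,
    config: PhaseConfig | None = None,
    max_states: int = DEFAULT_STATE_CAP,
) -> PhaseStats:
    """Distinct transitions of the pruned async graph, grouped by source phase.

    A transition belongs to phase P when its source state is reachable
    from the cycle start with latch P; a transition reachable under
    several latches is counted once, for the earliest phase.  Counts sum
    to the total edge count of the pruned reachable graph.
    """
    if config is None:
        config = four_phase_config()
    h, start, end, _ = enumerate_cycle_paths(model, max_states)
    phase_of = _phase_index_fn(model, config)
    k = len(config.markers)
    # BFS over (state, latched phase)
    start_phase = phase_of(start, 0)
    seen = {(start, start_phase)}
    frontier = [(start, start_phase)]
    edge_phase: dict[tuple[State, State], int] = {}
    while frontier:
        v, p = frontier.pop(0)
        if v == end:
            continue
        for w in h.successors(v):
            key = (v, w)
            if key not in edge_phase or p < edge_phase[key]:
                edge_phase[key] = p
            q = phase_of(w, p)
            if (w, q) not in seen:
                seen.add((w, q))
                frontier.append((w, q))
    stats = PhaseStats(phases=config.names, n_paths=0)
    for name in config.names:
        stats.transition_counts[name] = 0
    for (v, w), p in edge_phase.items():
        stats.transition_counts[config.names[p]] += 1
    return stats


def stats_to_tsv(stats: PhaseStats) -> str:
    lines = ["phase\tmean_length\tvariance"]
    for name in stats.phases:
        lines.append(f"{name}\t{stats.mean[name]:.2f}\t{stats.variance[name]:.2f}")
    return "\n".join(lines) + "\n"


def counts_to_tsv(stats: PhaseStats) -> str:
    lines = ["phase\tn_transitions"]
    for name in stats.phases:
        lines.append(f"{name}\t{stats.transition_counts[name]}")
    return "\n".join(lines) + "\n"
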