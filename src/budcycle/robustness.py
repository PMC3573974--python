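"""Random edge-mutation screening for timing robustness.

A mutant network differs from its base model by a fixed number of
elementary edge edits (the mutation *distance*): deleting an existing
edge, adding an absent one, or re-weighting an existing edge, drawn from
the edge slots related to one cell-cycle phase.  Each mutant is screened
for the core timing-robustness property — preservation of the stationary
G1 state as the global attractor under fully asynchronous updating — and
the fraction of robust mutants is reported per (phase, distance) cell.

"Related to a phase" is defined through the reference synchronous
trajectory: an edge slot belongs to a phase when either endpoint changes
level during that phase's segment.  A user-supplied edge set may replace
this default.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from fractions import Fraction

from .checking import check_global_attractor
from .dynamics import simulate
from .netdef import EdgeSpec, LI_WEIGHTS, MULTILEVEL_WEIGHTS, NetworkModel
from .phases import PhaseConfig, four_phase_config, label_trajectory
from .statespace import DEFAULT_STATE_CAP, StateCapExceeded

__all__ = [
    "EdgeEdit",
    "MutationSpec",
    "ScreenResult",
    "phase_related_edges",
    "generate_mutants",
    "screen",
    "screen_to_tsv",
]


@dataclass(frozen=True)
class EdgeEdit:
    """One elementary edit: delete, add, or reweight a single edge slot."""

    kind: str  # "delete" | "add" | "reweight"
    source: str
    target: str
    weight: Fraction | None = None  # new weight for add/reweight


@dataclass(frozen=True)
class MutationSpec:
    phase: str
    distance: int
    operations: tuple[EdgeEdit, ...]
    seed: int


@dataclass
class ScreenResult:
    phase: str
    distance: int
    n_mutants: int
    n_robust: int
    seed: int
    verdicts: list[bool] = field(default_factory=list)
    n_cap_errors: int = 0

    @property
    def fraction(self) -> float:
        return self.n_robust / self.n_mutants


def phase_related_edges(
    model: NetworkModel,
    phase: str,
    config: PhaseConfig | None = None,
) -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    """Edge slots related to ``phase``: (existing edges, absent candidate pairs).

    A node is active in a phase when its level changes during that
    phase's segment of the reference synchronous trajectory from the
    stimulated G1 state.  Existing edges touching an active node are
    editable; ordered pairs among active nodes without an edge are
    candidates for addition (self-pairs excluded).
    """
    if config is None:
        config = four_phase_config()
    if phase not in config.names:
        raise ValueError(f"unknown phase {phase!r}; config has {config.names}")
    traj = simulate(model, model.stimulated_g1, "sync", max_steps=200)
    labels = label_trajectory(model, traj, config)
    changing: set[str] = set()
    for t, label in enumerate(labels):
        if label != phase or t + 1 >= len(traj.states):
            continue
        a, b = traj.states[t], traj.states[t + 1]
        for i, name in enumerate(model.node_names):
            if a[i] != b[i]:
                changing.add(name)
    existing = {
        (e.source, e.target)
        for e in model.edges
        if e.source in changing or e.target in changing
    }
    present = {(e.source, e.target) for e in model.edges}
    absent = {
        (a, b)
        for a in sorted(changing)
        for b in sorted(changing)
        if a != b and (a, b) not in present
    }
    return existing, absent


def _weight_alphabet(model: NetworkModel) -> list[Fraction]:
    ab = LI_WEIGHTS if model.semantics == "li_binary" else MULTILEVEL_WEIGHTS
    return sorted(ab)


def generate_mutants(
    model: NetworkModel,
    phase: str,
    distance: int,
    n: int,
    seed: int,
    config: PhaseConfig | None = None,
    edge_slots: tuple[set, set] | None = None,
) -> list[tuple[MutationSpec, NetworkModel]]:
    """``n`` seeded random mutants at the given edit distance.

    Sampling is with replacement across mutants (duplicates allowed); the
    edits within one mutant target distinct edge slots.  Re-weighting
    draws uniformly from alphabet values other than the current weight,
    keeping the original sign with probability 1/2.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 1 <= distance <= 3:
        raise ValueError("distance must be in 1..3")
    existing, absent = (
        edge_slots if edge_slots is not None else phase_related_edges(model, phase, config)
    )
    slots = sorted(existing | absent)
    if len(slots) < distance:
        raise ValueError(
            f"phase {phase!r} has only {len(slots)} editable edge slots"
        )
    alphabet = _weight_alphabet(model)
    magnitudes = sorted({abs(w) for w in alphabet})
    weight_of = {(e.source, e.target): e.weight for e in model.edges}
    rng = random.Random(seed)
    out = []
    for _ in range(n):
        chosen = rng.sample(slots, distance)
        edits = []
        for src, dst in chosen:
            if (src, dst) in existing and (src, dst) in weight_of:
                cur = weight_of[(src, dst)]
                if rng.random() < 0.5:
                    edits.append(EdgeEdit("delete", src, dst))
                else:
                    sign = 1 if (cur > 0) == (rng.random() < 0.5) else -1
                    # uniform over alphabet values != current, sign kept w.p. 1/2
                    choices = [w for w in alphabet if w != cur]
                    new = rng.choice(
                        [w for w in choices if (w > 0) == (sign > 0)] or choices
                    )
                    edits.append(EdgeEdit("reweight", src, dst, new))
            else:
                mag = rng.choice(magnitudes)
                sign = 1 if rng.random() < 0.5 else -1
                edits.append(EdgeEdit("add", src, dst, sign * mag))
        spec = MutationSpec(phase, distance, tuple(edits), seed)
        out.append((spec, _apply(model, spec)))
    return out


def _apply(model: NetworkModel, spec: MutationSpec) -> NetworkModel:
    edges = {(e.source, e.target): e for e in model.edges}
    for op in spec.operations:
        key = (op.source, op.target)
        if op.kind == "delete":
            edges.pop(key, None)
        else:
            edges[key] = EdgeSpec(op.source, op.target, op.weight)
    return model.with_edges(edges.values(), name=f"{model.name}~{spec.phase}d{spec.distance}")


def screen(
    mutants: list[tuple[MutationSpec, NetworkModel]],
    initial=None,
    target=None,
    max_states: int = DEFAULT_STATE_CAP,
) -> ScreenResult:
    """Global-attractor check per mutant; returns the robust fraction.

    Mutants for which the stationary state is no longer a fixed point, or
    whose exploration exceeds the cap, count as non-robust (the cap case
    is flagged separately).
    """
    if not mutants:
        raise ValueError("empty mutant list")
    spec0 = mutants[0][0]
    verdicts = []
    caps = 0
    for spec, m in mutants:
        ini = initial if initial is not None else m.stimulated_g1
        tgt = target if target is not None else m.stationary_g1
        try:
            v = check_global_attractor(m, ini, tgt, max_states=max_states)
            verdicts.append(v.passed)
        except ValueError:
            verdicts.append(False)  # target no longer a fixed point
        except StateCapExceeded:
            verdicts.append(False)
            caps += 1
    return ScreenResult(
        phase=spec0.phase,
        distance=spec0.distance,
        n_mutants=len(mutants),
        n_robust=sum(verdicts),
        seed=spec0.seed,
        verdicts=verdicts,
        n_cap_errors=caps,
    )


def screen_to_tsv(results: list[ScreenResult]) -> str:
    lines = ["phase\tdistance\tn\tn_robust\tfraction\tseed"]
    for r in results:
        lines.append(
            f"{r.phase}\t{r.distance}\t{r.n_mutants}\t{r.n_robust}"
            f"\t{r.fraction:.2f}\t{r.seed}"
        )
    return "\n".join(lines) + "\n"
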