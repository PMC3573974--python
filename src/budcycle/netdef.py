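"""Network definition: multi-valued threshold networks, file I/O, bundled fixtures.

A :class:`NetworkModel` is a weighted signed digraph over named nodes.  Each
node carries a small number of discrete activity levels (binary, or ternary
for graded regulators such as Clb2), and each edge an exact rational weight
from a small alphabet.  Two update semantics are supported:

``li_binary``
    The classic threshold rule for binary nodes: a node switches ON when the
    weighted input sum is positive, OFF when negative, and on a tie either
    keeps its value or decays to 0 if flagged ``self_degrading``.

``multilevel``
    The graded rule: a node at level *s* steps up by one when the input sum
    reaches the entry threshold of level *s+1* (default 1/2, 3/2), steps
    down by one when the sum falls below the entry threshold of its current
    level, and otherwise holds.  Absent sustaining input, an active node
    therefore decays — self-degradation is built in.

Weights and thresholds are :class:`fractions.Fraction` throughout: the
alphabet contains 1/3, which has no exact binary floating-point
representation, and threshold comparisons at exactly 1/2 and 3/2 must be
bit-exact.  Internally everything is scaled by 6 to integers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "NodeSpec",
    "EdgeSpec",
    "NetworkModel",
    "State",
    "ValidationError",
    "MULTILEVEL_WEIGHTS",
    "LI_WEIGHTS",
    "load_network",
    "save_network",
    "loads_network",
    "dumps_network",
    "bundled_fixture",
    "bundled_fixtures",
    "CANONICAL_NODES",
]

#: Canonical node order used for printed state vectors (Table layout order).
CANONICAL_NODES = (
    "Cln3", "MBF", "SBF", "Cln2", "Cdh1", "Swi5",
    "Cdc20", "Clb5", "Sic1", "Clb2", "Mcm1",
)

#: Admissible edge-weight magnitudes for the multilevel semantics.
MULTILEVEL_WEIGHTS = frozenset(
    Fraction(s) * m for s in (1, -1) for m in (Fraction(1, 3), Fraction(1), Fraction(3))
)

#: Admissible weights for the Li binary semantics.
LI_WEIGHTS = frozenset((Fraction(1), Fraction(-1)))


class ValidationError(ValueError):
    """A model definition violates the schema or an invariant."""


@dataclass(frozen=True)
class NodeSpec:
    """One node: name, number of levels, decay flag, level-entry thresholds.

    ``thresholds[k]`` is the input sum required to *enter* level ``k+1``;
    the list is strictly increasing and has ``max_level`` entries.
    """

    name: str
    max_level: int = 1
    self_degrading: bool = False
    thresholds: tuple[Fraction, ...] = ()

    def __post_init__(self) -> None:
        if self.max_level not in (1, 2):
            raise ValidationError(
                f"node {self.name!r}: max_level must be 1 or 2, got {self.max_level}"
            )
        th = tuple(Fraction(t) for t in self.thresholds)
        if len(th) != self.max_level:
            raise ValidationError(
                f"node {self.name!r}: needs {self.max_level} thresholds, got {len(th)}"
            )
        if any(b <= a for a, b in zip(th, th[1:])):
            raise ValidationError(
                f"node {self.name!r}: thresholds must be strictly increasing: {th}"
            )
        object.__setattr__(self, "thresholds", th)


def _default_thresholds(semantics: str, max_level: int) -> tuple[Fraction, ...]:
    if semantics == "li_binary":
        return (Fraction(0),)
    return tuple(Fraction(2 * k - 1, 2) for k in range(1, max_level + 1))


@dataclass(frozen=True, order=True)
class EdgeSpec:
    """A signed, weighted regulatory edge ``source -> target``."""

    source: str
    target: str
    weight: Fraction

    def __post_init__(self) -> None:
        w = Fraction(self.weight)
        if w == 0:
            raise ValidationError(f"edge {self.source}->{self.target}: weight 0")
        object.__setattr__(self, "weight", w)


@dataclass(frozen=True, order=True)
class State:
    """An assignment of an integer activity level to every node.

    Levels are stored in the owning model's node order; ``State`` is
    hashable and totally ordered so that state sets can be enumerated
    canonically.
    """

    levels: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.levels)

    def __getitem__(self, i: int) -> int:
        return self.levels[i]

    def render(self, sep: str = " ") -> str:
        return sep.join(str(v) for v in self.levels)


class NetworkModel:
    """A validated multi-valued threshold network with named reference states."""

    def __init__(
        self,
        name: str,
        semantics: str,
        nodes: Sequence[NodeSpec],
        edges: Iterable[EdgeSpec],
        states: Mapping[str, Mapping[str, int]] | None = None,
    ) -> None:
        if semantics not in ("li_binary", "multilevel"):
            raise ValidationError(f"unknown semantics {semantics!r}")
        self.name = name
        self.semantics = semantics
        self.nodes: tuple[NodeSpec, ...] = tuple(nodes)
        self.node_names: tuple[str, ...] = tuple(n.name for n in self.nodes)
        if len(set(self.node_names)) != len(self.node_names):
            raise ValidationError("duplicate node names")
        self.index: dict[str, int] = {n: i for i, n in enumerate(self.node_names)}
        alphabet = LI_WEIGHTS if semantics == "li_binary" else MULTILEVEL_WEIGHTS
        self.edges: tuple[EdgeSpec, ...] = tuple(sorted(edges))
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            for endpoint in (e.source, e.target):
                if endpoint not in self.index:
                    raise ValidationError(
                        f"edge {e.source}->{e.target}: unknown node {endpoint!r}"
                    )
            if e.weight not in alphabet:
                raise ValidationError(
                    f"edge {e.source}->{e.target}: weight {e.weight} not in the "
                    f"{semantics} alphabet"
                )
            if (e.source, e.target) in seen:
                raise ValidationError(f"duplicate edge {e.source}->{e.target}")
            seen.add((e.source, e.target))
        if semantics == "li_binary":
            for n in self.nodes:
                if n.max_level != 1:
                    raise ValidationError(
                        f"node {n.name!r}: li_binary semantics requires binary nodes"
                    )
        self.reference_states: dict[str, State] = {}
        for key, levels in (states or {}).items():
            self.reference_states[key] = self.state_from_dict(levels)

    # -- state helpers ---------------------------------------------------

    def state_from_dict(self, levels: Mapping[str, int]) -> State:
        unknown = set(levels) - set(self.node_names)
        if unknown:
            raise ValidationError(f"state refers to unknown nodes {sorted(unknown)}")
        vec = []
        for n in self.nodes:
            v = int(levels.get(n.name, 0))
            if not 0 <= v <= n.max_level:
                raise ValidationError(
                    f"state: level {v} out of range for node {n.name!r}"
                )
            vec.append(v)
        return State(tuple(vec))

    def state_to_dict(self, state: State) -> dict[str, int]:
        return dict(zip(self.node_names, state.levels))

    @property
    def stationary_g1(self) -> State:
        return self.reference_states["stationary_g1"]

    @property
    def stimulated_g1(self) -> State:
        return self.reference_states["stimulated_g1"]

    @property
    def max_levels(self) -> tuple[int, ...]:
        return tuple(n.max_level for n in self.nodes)

    def state_space_size(self) -> int:
        size = 1
        for n in self.nodes:
            size *= n.max_level + 1
        return size

    def all_states(self) -> Iterable[State]:
        """Enumerate the full state space in canonical (mixed-radix) order."""
        radix = [n.max_level + 1 for n in self.nodes]
        total = self.state_space_size()
        for code in range(total):
            vec, c = [], code
            for r in radix:
                vec.append(c % r)
                c //= r
            yield State(tuple(vec))

    # -- equality / mutation --------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NetworkModel):
            return NotImplemented
        return (
            self.name == other.name
            and self.semantics == other.semantics
            and self.nodes == other.nodes
            and self.edges == other.edges
            and self.reference_states == other.reference_states
        )

    def __repr__(self) -> str:
        return (
            f"<NetworkModel {self.name!r} ({self.semantics}): "
            f"{len(self.nodes)} nodes, {len(self.edges)} edges>"
        )

    def with_edges(self, edges: Iterable[EdgeSpec], name: str | None = None) -> "NetworkModel":
        """A copy of this model with a replaced edge list (used by mutation)."""
        return NetworkModel(
            name=name or self.name,
            semantics=self.semantics,
            nodes=self.nodes,
            edges=edges,
            states={k: self.state_to_dict(v) for k, v in self.reference_states.items()},
        )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _frac_to_token(x: Fraction) -> str:
    return str(x.numerator) if x.denominator == 1 else f"{x.numerator}/{x.denominator}"


def _token_to_frac(tok: str | int) -> Fraction:
    if isinstance(tok, int):
        return Fraction(tok)
    if isinstance(tok, float):
        raise ValidationError(
            f"weight {tok!r} given as float; use exact rational string tokens"
        )
    return Fraction(tok)


def _model_to_obj(model: NetworkModel) -> dict:
    return {
        "name": model.name,
        "semantics": model.semantics,
        "nodes": [
            {
                "name": n.name,
                "max_level": n.max_level,
                "self_degrading": n.self_degrading,
                "thresholds": [_frac_to_token(t) for t in n.thresholds],
            }
            for n in model.nodes
        ],
        "edges": [
            {"from": e.source, "to": e.target, "weight": _frac_to_token(e.weight)}
            for e in sorted(model.edges)
        ],
        "states": {
            key: {
                n: v
                for n, v in sorted(model.state_to_dict(st).items())
                if v != 0
            }
            for key, st in sorted(model.reference_states.items())
        },
    }


def _model_from_obj(obj: dict, origin: str = "<memory>") -> NetworkModel:
    try:
        semantics = obj["semantics"]
        nodes = []
        for rec in obj["nodes"]:
            max_level = int(rec.get("max_level", 1))
            th = rec.get("thresholds")
            thresholds = (
                tuple(_token_to_frac(t) for t in th)
                if th is not None
                else _default_thresholds(semantics, max_level)
            )
            nodes.append(
                NodeSpec(
                    name=rec["name"],
                    max_level=max_level,
                    self_degrading=bool(rec.get("self_degrading", False)),
                    thresholds=thresholds,
                )
            )
        edges = [
            EdgeSpec(rec["from"], rec["to"], _token_to_frac(rec["weight"]))
            for rec in obj["edges"]
        ]
        states = obj.get("states", {})
        return NetworkModel(
            name=obj.get("name", Path(origin).stem),
            semantics=semantics,
            nodes=nodes,
            edges=edges,
            states=states,
        )
    except KeyError as exc:
        raise ValidationError(f"{origin}: missing required field {exc}") from exc


def dumps_network(model: NetworkModel, format: str = "json") -> str:
    """Canonical serialization (nodes in declared order, edges sorted)."""
    if format == "json":
        return json.dumps(_model_to_obj(model), indent=1) + "\n"
    if format == "tsv":
        lines = [f"#name\t{model.name}", f"#semantics\t{model.semantics}"]
        for n in model.nodes:
            lines.append(
                "#node\t{}\t{}\t{}\t{}".format(
                    n.name,
                    n.max_level,
                    int(n.self_degrading),
                    ",".join(_frac_to_token(t) for t in n.thresholds),
                )
            )
        for key, st in sorted(model.reference_states.items()):
            lines.append(f"#state\t{key}\t{st.render(',')}")
        for e in sorted(model.edges):
            lines.append(f"{e.source}\t{e.target}\t{_frac_to_token(e.weight)}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {format!r}")


def loads_network(text: str, format: str = "json", origin: str = "<memory>") -> NetworkModel:
    if format == "json":
        return _model_from_obj(json.loads(text), origin)
    if format == "tsv":
        name, semantics = origin, "multilevel"
        nodes, edges, states = [], [], {}
        node_meta: list[tuple[str, int, bool, tuple[Fraction, ...] | None]] = []
        state_rows: list[tuple[str, str]] = []
        for ln, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t")
            if parts[0] == "#name":
                name = parts[1]
            elif parts[0] == "#semantics":
                semantics = parts[1]
            elif parts[0] == "#node":
                if len(parts) < 2:
                    raise ValidationError(f"{origin}:{ln}: malformed #node record")
                nm = parts[1]
                maxlev = int(parts[2]) if len(parts) > 2 else 1
                sd = bool(int(parts[3])) if len(parts) > 3 else False
                th = (
                    tuple(_token_to_frac(t) for t in parts[4].split(","))
                    if len(parts) > 4 and parts[4]
                    else None
                )
                node_meta.append((nm, maxlev, sd, th))
            elif parts[0] == "#state":
                state_rows.append((parts[1], parts[2]))
            elif parts[0].startswith("#"):
                continue
            else:
                if len(parts) != 3:
                    raise ValidationError(
                        f"{origin}:{ln}: expected 'source<TAB>target<TAB>weight'"
                    )
                edges.append(EdgeSpec(parts[0], parts[1], _token_to_frac(parts[2])))
        for nm, maxlev, sd, th in node_meta:
            nodes.append(
                NodeSpec(
                    nm, maxlev, sd,
                    th if th is not None else _default_thresholds(semantics, maxlev),
                )
            )
        order = [n.name for n in nodes]
        for key, row in state_rows:
            levels = [int(v) for v in row.split(",")]
            states[key] = dict(zip(order, levels))
        return NetworkModel(name, semantics, nodes, edges, states)
    raise ValueError(f"unknown format {format!r}")


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    return "tsv" if path.suffix in (".tsv", ".txt") else "json"


def load_network(path: str | Path, format: str | None = None) -> NetworkModel:
    """Load and validate a network model from a JSON or TSV file."""
    path = Path(path)
    fmt = _infer_format(path, format)
    return loads_network(path.read_text(), fmt, origin=str(path))


def save_network(model: NetworkModel, path: str | Path, format: str | None = None) -> None:
    """Write the canonical serialization of ``model`` to ``path``."""
    path = Path(path)
    fmt = _infer_format(path, format)
    path.write_text(dumps_network(model, fmt))


# ---------------------------------------------------------------------------
# bundled fixtures
# ---------------------------------------------------------------------------

_FIXTURE_NAMES = ("li", "mangla", "proposed")


def bundled_fixture(name: str) -> NetworkModel:
    """Load one of the bundled yeast cell-cycle models: li, mangla, proposed."""
    if name not in _FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {_FIXTURE_NAMES}")
    text = resources.files("budcycle.models").joinpath(f"{name}.json").read_text()
    return loads_network(text, "json", origin=name)


def bundled_fixtures() -> list[NetworkModel]:
    """The three bundled yeast models, in order li, mangla, proposed."""
    return [bundled_fixture(n) for n in _FIXTURE_NAMES]
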