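"""Checkpoint property checking, counterexample validity, SMV export."""

import itertools
import random
from fractions import Fraction

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from budcycle import (
    GlobalAttractorProperty,
    PrecedenceProperty,
    ResponseProperty,
    async_successors,
    check_all,
    check_global_attractor,
    check_precedence,
    check_response,
    default_property_set,
    export_nusmv,
    reachable_graph,
)
from budcycle.netdef import EdgeSpec, NetworkModel, NodeSpec, State


def _replayable(model, traj):
    """Every counterexample step must be a legal asynchronous successor."""
    for a, b in zip(traj.states, traj.states[1:]):
        assert b in {s for _, s in async_successors(model, a)}


class TestPrecedence:
    def test_two_node_chain_structurally_safe(self, two_node_chain):
        start = two_node_chain.state_from_dict({})
        prop = PrecedenceProperty(("A", 1), ("B", 1), "a_before_b")
        # B cannot rise without A: property passes from the empty state
        assert check_precedence(two_node_chain, start, prop).passed

    def test_mangla_hazard_counterexample(self, mangla):
        prop = PrecedenceProperty(("Clb2", 1), ("Cdc20", 1), "clb2_first")
        v = check_precedence(mangla, mangla.stimulated_g1, prop)
        assert not v.passed
        traj = v.counterexample
        _replayable(mangla, traj)
        i_clb2, i_cdc20 = mangla.index["Clb2"], mangla.index["Cdc20"]
        t_cdc20 = min(t for t, s in enumerate(traj.states) if s[i_cdc20] >= 1)
        assert all(s[i_clb2] == 0 for s in traj.states[: t_cdc20 + 1]), (
            "Cdc20 must rise while Clb2 is still off"
        )
        # Mcm1 rises before Clb2 on the witness (the documented mechanism)
        i_mcm1 = mangla.index["Mcm1"]
        assert any(s[i_mcm1] >= 1 for s in traj.states[: t_cdc20 + 1])

    def test_proposed_passes_metaphase_precedence(self, proposed):
        for ante in (("Clb2", 1), ("Mcm1", 1)):
            prop = PrecedenceProperty(ante, ("Cdc20", 1), "x")
            assert check_precedence(proposed, proposed.stimulated_g1, prop).passed

    def test_counterexample_is_shortest(self, li):
        prop = PrecedenceProperty(("Clb2", 1), ("Cdc20", 1), "clb2_first")
        v = check_precedence(li, li.stimulated_g1, prop)
        assert not v.passed
        # BFS depth equals the minimum number of async updates needed to
        # reach a Cdc20-active state while Clb2 never rose
        assert v.counterexample.n_steps == 7


class TestResponse:
    def test_proposed_swi5_response(self, proposed):
        prop = ResponseProperty(("Cdc20", 1), ("Swi5", 2), "swi5_follows")
        assert check_response(proposed, proposed.stimulated_g1, prop).passed

    def test_mangla_swi5_response_fails(self, mangla):
        prop = ResponseProperty(("Cdc20", 1), ("Swi5", 1), "swi5_follows")
        v = check_response(mangla, mangla.stimulated_g1, prop)
        assert not v.passed
        _replayable(mangla, v.counterexample)

    def test_oscillator_obligation_outside_cycle_fails(self, two_node_chain):
        """A trigger whose obligation is unreachable yields a failure with a
        witness staying forever in the absorbing/looping region."""
        m = two_node_chain
        start = m.reference_states["start"]  # A=1 sustains itself, drives B
        # B never decays once on (A keeps it above threshold), so the
        # obligation "B returns to 0" is unreachable from the trigger
        prop = ResponseProperty(("A", 1), ("B", 0), "b_off_again")
        with pytest.raises(ValueError):
            # level-0 obligations are not expressible as >=; use named state
            check_response(m, start, prop)

    def test_trivial_obligation_passes(self, async_oscillator):
        m = async_oscillator
        start = m.reference_states["start"]
        # C stays at 1 on the whole cycle: obligation holds immediately
        prop = ResponseProperty(("C", 1), ("C", 1), "trivial")
        assert check_response(m, start, prop).passed

    def test_response_trigger_to_named_state(self, proposed):
        prop = ResponseProperty(("Cdc20", 1), "stationary_g1", "returns")
        assert check_response(proposed, proposed.stimulated_g1, prop).passed


class TestGlobalAttractor:
    def test_proposed_passes(self, proposed):
        v = check_global_attractor(
            proposed, proposed.stimulated_g1, proposed.stationary_g1
        )
        assert v.passed

    def test_mangla_passes(self, mangla):
        v = check_global_attractor(mangla, mangla.stimulated_g1, mangla.stationary_g1)
        assert v.passed

    def test_li_fails_with_replayable_witness(self, li):
        v = check_global_attractor(li, li.stimulated_g1, li.stationary_g1)
        assert not v.passed
        _replayable(li, v.counterexample)
        end = v.counterexample.states[-1]
        if v.loop_start is None:
            # path to a wrong absorbing state
            assert end != li.stationary_g1
            assert async_successors(li, end) == []

    def test_oscillator_fails_with_lasso(self, async_oscillator):
        m = async_oscillator
        start = m.reference_states["start"]
        # the all-off state with C=1... C=1,A=B=0 is not fixed; use a 2-node
        # fixed target outside the cycle: no fixed point is reachable, so
        # verify the lasso shape against the one fixed point of the model
        fixed = m.state_from_dict({})  # all zero: C=0 stays, A,B stay
        v = check_global_attractor(m, start, fixed)
        assert not v.passed
        assert v.loop_start is not None
        loop = v.counterexample.states[v.loop_start:]
        assert loop[0] == loop[-1] or len(loop) >= 2
        _replayable(m, v.counterexample)

    def test_target_must_be_fixed_point(self, li):
        with pytest.raises(ValueError):
            check_global_attractor(li, li.stimulated_g1, li.stimulated_g1)


class TestDefaultPropertySet:
    def test_proposed_all_pass(self, proposed):
        assert all(v.passed for v in check_all(proposed))

    def test_mangla_fails_exactly_two_groups(self, mangla):
        verdicts = check_all(mangla)
        failing_groups = {v.group for v in verdicts if not v.passed}
        assert failing_groups == {"m_metaphase", "m_telophase"}

    def test_li_fails_metaphase_and_global(self, li):
        verdicts = check_all(li)
        failing_groups = {v.group for v in verdicts if not v.passed}
        assert "m_metaphase" in failing_groups
        assert "global" in failing_groups

    def test_failures_carry_replayable_counterexamples(self, li, mangla):
        for m in (li, mangla):
            for v in check_all(m):
                if not v.passed and v.counterexample is not None:
                    _replayable(m, v.counterexample)

    def test_monotonicity_sync_schedule(self, proposed):
        """A precedence property passing on the full async graph cannot be
        violated by the synchronous schedule (one particular interleaving)."""
        from budcycle import simulate

        traj = simulate(proposed, proposed.stimulated_g1, "sync", 100)
        for prop in default_property_set(proposed):
            if not isinstance(prop, PrecedenceProperty):
                continue
            ia = proposed.index[prop.antecedent[0]]
            ic = proposed.index[prop.consequent[0]]
            seen = False
            for s in traj.states:
                seen = seen or s[ia] >= prop.antecedent[1]
                if s[ic] >= prop.consequent[1]:
                    assert seen


class TestSMVExport:
    def test_eleven_fairness_lines(self, proposed):
        text = export_nusmv(proposed)
        fairness = [l for l in text.splitlines() if l.startswith("FAIRNESS")]
        assert len(fairness) == 11
        for name in proposed.node_names:
            assert f"FAIRNESS turn = {name}" in text

    def test_spec_lines_use_declared_variables_only(self, mangla):
        text = export_nusmv(mangla)
        declared = set(mangla.node_names) | {"turn", "TRUE", "AG", "AF", "SPEC"}
        import re

        for line in text.splitlines():
            if not line.startswith("SPEC"):
                continue
            for ident in re.findall(r"[A-Za-z_][A-Za-z0-9_]*", line):
                assert ident in declared or ident.startswith("seen_") or ident in (
                    "SPEC", "AG", "AF",
                )

    def test_variable_ranges_match_levels(self, proposed):
        text = export_nusmv(proposed)
        assert "Clb2 : 0..2;" in text
        assert "Swi5 : 0..2;" in text
        assert "Cln3 : 0..1;" in text

    def test_structure_is_balanced(self, li):
        text = export_nusmv(li)
        assert text.count("case") == text.count("esac")
        assert text.startswith("MODULE main")


# -- brute-force oracle equivalence -----------------------------------------

def _random_small_model(rng: random.Random, n_nodes: int) -> NetworkModel:
    names = [f"N{i}" for i in range(n_nodes)]
    nodes = [NodeSpec(nm, 1, False, (Fraction(1, 2),)) for nm in names]
    edges = [
        EdgeSpec(s, t, rng.choice([Fraction(1, 3), Fraction(1), Fraction(3)]) * rng.choice([1, -1]))
        for s in names
        for t in names
        if rng.random() < 0.5
    ]
    return NetworkModel("rand", "multilevel", nodes, edges, states={})


def _oracle_precedence(model, initial, prop) -> bool:
    """Exhaustive path check: explore every (state, seen-antecedent) pair via
    plain graph search on the explicit product — an independent formulation
    of the same semantics used to cross-check the BFS monitor construction."""
    ia = model.index[prop.antecedent[0]]
    ic = model.index[prop.consequent[0]]
    la, lc = prop.antecedent[1], prop.consequent[1]
    g = nx.DiGraph()
    init = (initial, initial[ia] >= la)
    stack, seen = [init], {init}
    while stack:
        state, flag = stack.pop()
        if state[ic] >= lc and not flag:
            return False
        for _, succ in async_successors(model, state):
            nxt = (succ, flag or succ[ia] >= la)
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return True


@settings(max_examples=100, deadline=None)
@given(st.integers(0, 10**6))
def test_precedence_matches_bruteforce_oracle(seed):
    rng = random.Random(seed)
    m = _random_small_model(rng, rng.randint(2, 5))
    initial = State(tuple(rng.randint(0, 1) for _ in m.nodes))
    a, c = rng.sample(list(m.node_names), 2) if len(m.nodes) > 1 else (None, None)
    prop = PrecedenceProperty((a, 1), (c, 1), "p")
    fast = check_precedence(m, initial, prop).passed
    slow = _oracle_precedence(m, initial, prop)
    assert fast == slow
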