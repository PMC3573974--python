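"""Update rules, stepping contracts, and simulation determinism."""

import random
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from budcycle import async_successors, local_target, simulate, sync_step
from budcycle.dynamics import is_fixed_point, trajectory_to_tsv
from budcycle.netdef import EdgeSpec, NetworkModel, NodeSpec, State


class TestLocalTarget:
    def test_multilevel_increment_at_threshold(self, two_node_chain):
        # A at 1 sustains itself (sum 1 >= 1/2) and drives B up
        s = two_node_chain.reference_states["start"]
        assert local_target(two_node_chain, s, "A") == 1
        assert local_target(two_node_chain, s, "B") == 1

    def test_no_decrement_below_zero(self, two_node_chain):
        s = two_node_chain.state_from_dict({})
        assert local_target(two_node_chain, s, "A") == 0
        assert local_target(two_node_chain, s, "B") == 0

    def test_li_self_degradation_on_tie(self, li):
        # a self-degrading node with zero input sum decays from 1
        s = li.state_from_dict({"Cln3": 1})
        assert local_target(li, s, "Cln3") == 0

    def test_li_tie_retains_without_flag(self, li):
        # Cdh1 is not self-degrading: zero input sum retains its level
        s = li.state_from_dict({"Cdh1": 1})
        assert local_target(li, s, "Cdh1") == 1

    def test_unknown_node_raises(self, li):
        with pytest.raises(KeyError):
            local_target(li, li.stationary_g1, "Nope")


class TestStepping:
    def test_fixed_point_maps_to_itself(self, li, mangla, proposed):
        for m in (li, mangla, proposed):
            assert sync_step(m, m.stationary_g1) == m.stationary_g1
            assert async_successors(m, m.stationary_g1) == []

    def test_sync_cycle_returns_to_g1(self, li, mangla, proposed):
        for m in (li, mangla, proposed):
            traj = simulate(m, m.stimulated_g1, "sync", 100)
            assert traj.states[-1] == m.stationary_g1
            assert not traj.hit_step_cap

    def test_async_single_change_per_step(self, mangla):
        traj = simulate(mangla, mangla.stimulated_g1, "async", 500, seed=3)
        for a, b in zip(traj.states, traj.states[1:]):
            diffs = [i for i in range(len(a)) if a[i] != b[i]]
            assert len(diffs) == 1
            assert abs(a[diffs[0]] - b[diffs[0]]) == 1

    def test_async_seed_determinism(self, proposed):
        t1 = simulate(proposed, proposed.stimulated_g1, "async", 500, seed=11)
        t2 = simulate(proposed, proposed.stimulated_g1, "async", 500, seed=11)
        assert t1.states == t2.states and t1.update_sequence == t2.update_sequence

    def test_async_from_fixed_point_is_empty(self, proposed):
        traj = simulate(proposed, proposed.stationary_g1, "async", 10, seed=0)
        assert traj.n_steps == 0 and not traj.hit_step_cap

    def test_trajectory_tsv_has_canonical_columns(self, li):
        traj = simulate(li, li.stimulated_g1, "async", 20, seed=0)
        header = trajectory_to_tsv(li, traj).splitlines()[0].split("\t")
        assert header == ["step", *li.node_names, "updated_node"]


class TestFigureDynamics:
    """Temporal ordering of the graded positive feedback on the revised model."""

    def test_clb2_mcm1_positive_feedback_order(self, proposed):
        traj = simulate(proposed, proposed.stimulated_g1, "sync", 100)
        t_clb2_1 = traj.first_time_at(proposed, "Clb2", 1)
        t_clb2_2 = traj.first_time_at(proposed, "Clb2", 2)
        t_mcm1 = traj.first_time_at(proposed, "Mcm1", 1)
        assert t_clb2_1 is not None and t_mcm1 is not None and t_clb2_2 is not None
        assert t_clb2_1 < t_mcm1, "low Clb2 precedes Mcm1 transcription"
        assert t_clb2_2 > t_mcm1, "full Clb2 activation requires Mcm1"

    def test_swi5_two_stage_activation(self, proposed):
        traj = simulate(proposed, proposed.stimulated_g1, "sync", 100)
        t_swi5_1 = traj.first_time_at(proposed, "Swi5", 1)
        t_swi5_2 = traj.first_time_at(proposed, "Swi5", 2)
        t_mcm1 = traj.first_time_at(proposed, "Mcm1", 1)
        t_cdc20 = traj.first_time_at(proposed, "Cdc20", 1)
        assert t_mcm1 < t_swi5_1, "Mcm1 transcribes Swi5 at low level"
        assert t_cdc20 < t_swi5_2, "full Swi5 activation requires Cdc20"

    def test_hazard_branch_point(self, mangla, proposed):
        """After Clb5 rises, Mcm1 is co-eligible with Clb2 only in the graded
        predecessor; the revised weights leave Clb2 as the sole successor."""
        for m, mcm1_eligible in ((mangla, True), (proposed, False)):
            traj = simulate(m, m.stimulated_g1, "sync", 100)
            t = traj.first_time_at(m, "Clb5", 1)
            state = traj.states[t]
            enabled = {n for n, _ in async_successors(m, state)}
            assert "Clb2" in enabled
            assert ("Mcm1" in enabled) == mcm1_eligible


# -- property-based cross-check ---------------------------------------------

def _random_model(rng: random.Random, n_nodes: int) -> NetworkModel:
    names = [f"N{i}" for i in range(n_nodes)]
    nodes = []
    for nm in names:
        max_level = rng.choice([1, 1, 2])
        thresholds = (Fraction(1, 2), Fraction(3, 2))[:max_level]
        nodes.append(NodeSpec(nm, max_level, False, thresholds))
    edges = []
    for s in names:
        for t in names:
            if rng.random() < 0.4:
                w = rng.choice(
                    [Fraction(1, 3), Fraction(1), Fraction(3)]
                ) * rng.choice([1, -1])
                edges.append(EdgeSpec(s, t, w))
    return NetworkModel("rand", "multilevel", nodes, edges, states={})


@settings(max_examples=60, deadline=None)
@given(st.integers(0, 10_000), st.integers(2, 6))
def test_sync_step_matches_per_node_recomputation(seed, n_nodes):
    """The synchronous image equals applying every single-node update against
    the frozen predecessor — brute-force oracle on random small networks."""
    rng = random.Random(seed)
    m = _random_model(rng, n_nodes)
    for _ in range(5):
        levels = tuple(rng.randint(0, n.max_level) for n in m.nodes)
        state = State(levels)
        expected = State(
            tuple(local_target(m, state, nm) for nm in m.node_names)
        )
        assert sync_step(m, state) == expected
        # changes bounded by one level per node
        assert all(abs(a - b) <= 1 for a, b in zip(state.levels, expected.levels))


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 10_000))
def test_async_successors_are_exactly_value_changing_updates(seed):
    rng = random.Random(seed)
    m = _random_model(rng, 4)
    levels = tuple(rng.randint(0, n.max_level) for n in m.nodes)
    state = State(levels)
    succ = dict(async_successors(m, state))
    for i, nm in enumerate(m.node_names):
        t = local_target(m, state, nm)
        if t != state[i]:
            assert succ[nm].levels[i] == t
            assert sum(a != b for a, b in zip(succ[nm].levels, state.levels)) == 1
        else:
            assert nm not in succ
    if is_fixed_point(m, state):
        assert succ == {}
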