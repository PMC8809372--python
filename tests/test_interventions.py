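"""Minimal intervention set search: validity, minimality, oracle equivalence."""

import itertools

import pytest

from neuroqsp.interventions import (
    InterventionGoal,
    enumerate_minimal_interventions,
    intervention_target_frequencies,
    intervention_valid,
)
from neuroqsp.logic import parse_bnet, synchronous_step
from neuroqsp.synthetic import generate_random_network


def brute_force_goal_holds(network, clamps, goal_node, goal_value):
    """Oracle: dict-based exhaustive check over every free start state."""
    free = [n for n in network.nodes if n not in clamps]
    for idx in range(1 << len(free)):
        state = dict(clamps)
        state.update({n: (idx >> j) & 1 for j, n in enumerate(free)})
        seen = set()
        while tuple(state.items()) not in seen:
            seen.add(tuple(state.items()))
            state = synchronous_step(network, state, clamps)
        # walk the cycle
        cycle_start = state
        while True:
            if state[goal_node] != goal_value:
                return False
            state = synchronous_step(network, state, clamps)
            if state == cycle_start:
                break
    return True


def brute_force_minimal_sets(network, goal, values=(0,)):
    candidates = sorted(
        n for n in network.nodes if n != goal.goal_node and n not in goal.base_clamps
    )
    valid = []
    for size in range(0, goal.max_size + 1):
        for nodes in itertools.combinations(candidates, size):
            for assignment in itertools.product(values, repeat=size):
                clamps = dict(zip(nodes, assignment))
                merged = {**goal.base_clamps, **clamps}
                if brute_force_goal_holds(network, merged, goal.goal_node, goal.goal_value):
                    valid.append(clamps)
    minimal = []
    for v in valid:
        if not any(
            set(o.items()) < set(v.items()) for o in valid if o is not v
        ):
            minimal.append(v)
    return sorted(minimal, key=lambda c: (len(c), sorted(c.items())))


class TestValidity:
    def test_single_arm_block_is_insufficient(self, or_gate_network):
        goal = InterventionGoal("Apoptosis", 0, {"Proteasome": 0})
        # TNFa input can still be 1 in some start states
        assert not intervention_valid(or_gate_network, {"ROS": 0}, goal)

    def test_blocking_both_arms_is_valid(self, or_gate_network):
        goal = InterventionGoal("Apoptosis", 0, {"Proteasome": 0})
        assert intervention_valid(or_gate_network, {"TNFa": 0, "ROS": 0}, goal)

    def test_empty_intervention_valid_when_goal_already_holds(self):
        net = parse_bnet("A, A\nOut, A & !A")  # Out is constantly 0
        goal = InterventionGoal("Out", 0)
        assert intervention_valid(net, {}, goal)

    def test_clamping_goal_node_rejected(self, or_gate_network):
        goal = InterventionGoal("Apoptosis", 0, {"Proteasome": 0})
        with pytest.raises(ValueError, match="goal node"):
            intervention_valid(or_gate_network, {"Apoptosis": 0}, goal)

    def test_overlap_with_base_clamps_rejected(self, or_gate_network):
        goal = InterventionGoal("Apoptosis", 0, {"Proteasome": 0})
        with pytest.raises(ValueError, match="overlap"):
            intervention_valid(or_gate_network, {"Proteasome": 1}, goal)


class TestEnumeration:
    def test_or_gate_unique_pair(self, or_gate_network):
        goal = InterventionGoal("Apoptosis", 0, {"Proteasome": 0}, max_size=2)
        sets = enumerate_minimal_interventions(
            or_gate_network, goal, intervention_values="zero"
        )
        assert [s.clamps for s in sets] == [{"TNFa": 0, "ROS": 0}]
        assert sets[0].size == 2 and sets[0].minimal

    def test_no_solution_returns_empty(self, toggle_network):
        # neither single clamp of the other node can pin A to 0 in all attractors
        net = parse_bnet("A, A\nB, A | B")
        goal = InterventionGoal("B", 0, max_size=1, base_clamps={})
        sets = enumerate_minimal_interventions(net, goal, intervention_values="zero")
        assert sets == []

    def test_goal_already_held_reports_empty_set(self):
        net = parse_bnet("A, A\nOut, A & !A")
        sets = enumerate_minimal_interventions(net, InterventionGoal("Out", 0))
        assert len(sets) == 1 and sets[0].size == 0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle_zero_mode(self, seed):
        net = generate_random_network(N=7, K=2, seed=seed)
        goal = InterventionGoal(net.nodes[-1], 0, max_size=2)
        got = enumerate_minimal_interventions(net, goal, intervention_values="zero")
        expected = brute_force_minimal_sets(net, goal, values=(0,))
        got_sets = [s.clamps for s in got]
        if expected and not expected[0]:
            expected = [{}]  # empty-set convention
            assert got_sets == expected or (len(got) == 1 and got[0].size == 0)
        else:
            assert got_sets == expected

    @pytest.mark.parametrize("seed", [10, 11])
    def test_matches_brute_force_oracle_both_mode(self, seed):
        net = generate_random_network(N=6, K=2, seed=seed)
        goal = InterventionGoal(net.nodes[0], 1, max_size=2)
        got = enumerate_minimal_interventions(net, goal, intervention_values="both")
        expected = brute_force_minimal_sets(net, goal, values=(0, 1))
        if len(expected) == 1 and expected[0] == {}:
            assert len(got) == 1 and got[0].size == 0
        else:
            assert [s.clamps for s in got] == expected

    def test_minimality_no_valid_proper_subset(self, fixture_network):
        goal = InterventionGoal("Apoptosis", 0, {"Proteasome": 0, "NGF": 1}, max_size=3)
        sets = enumerate_minimal_interventions(
            fixture_network, goal, intervention_values="zero"
        )
        probe = sets[0]
        for k in probe.clamps:
            subset = {n: v for n, v in probe.clamps.items() if n != k}
            assert not intervention_valid(fixture_network, subset, goal)

    def test_supersets_of_minimal_sets_are_valid(self, or_gate_network):
        goal = InterventionGoal("Apoptosis", 0, {"Proteasome": 0}, max_size=2)
        minimal = {"TNFa": 0, "ROS": 0}
        superset = {**minimal, "ERstress": 0} if "ERstress" in or_gate_network.rules else minimal
        assert intervention_valid(or_gate_network, minimal, goal)


class TestFixtureStructure:
    def test_every_set_blocks_all_three_arms(self, fixture_network):
        goal = InterventionGoal("Apoptosis", 0, {"Proteasome": 0, "NGF": 1}, max_size=3)
        sets = enumerate_minimal_interventions(
            fixture_network, goal, intervention_values="zero"
        )
        assert len(sets) == 100 and all(s.size == 3 for s in sets)
        intrinsic = {"ROS", "ERstress", "ATF4", "CHOP", "ProApop"}
        tnfa_arm = {"TNFa", "TNFaR", "TRADD", "FADD", "Casp8"}
        nmda_arm = {"NMDA", "NMDAR", "nNOS", "NO"}
        for s in sets:
            members = set(s.clamps)
            assert members & intrinsic and members & tnfa_arm and members & nmda_arm


class TestTargetFrequencies:
    def test_hand_counts(self):
        from neuroqsp.interventions import InterventionSet

        sets = [
            InterventionSet({"A": 0, "B": 0}, 2, True, True, "exhaustive"),
            InterventionSet({"A": 0, "C": 0}, 2, True, True, "exhaustive"),
        ]
        out = intervention_target_frequencies(sets, {"bc": ["B", "C"], "none": []})
        assert out["nodes"].loc["A", "count"] == 2
        assert out["nodes"].loc["B", "count"] == 1
        assert out["groups"] == {"bc": 2, "none": 0}

    def test_unknown_group_node_rejected(self, or_gate_network):
        from neuroqsp.interventions import InterventionSet

        sets = [InterventionSet({"ROS": 0}, 1, True, True, "exhaustive")]
        with pytest.raises(KeyError, match="Missing"):
            intervention_target_frequencies(
                sets, {"g": ["Missing"]}, network=or_gate_network
            )

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            intervention_target_frequencies([])
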