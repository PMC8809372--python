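"""Minimal intervention analysis (MIA) on Boolean signaling networks.

An intervention is a set of node clamps (inhibitions: clamp to 0; constitutive
activations: clamp to 1) applied on top of fixed base clamps (e.g. drug
exposure and trophic-factor presence). An intervention is *valid* for a goal
``goal_node == goal_value`` if the goal holds in **every** state of **every**
attractor reachable from the verified initial states — exhaustively over the
free-node state space when small enough, otherwise over a seeded sample of
starts (flagged in the output). A valid set is *minimal* if no proper subset
is valid.

Enumeration is breadth-first over intervention sizes with superset pruning:
any candidate containing an already-reported minimal set cannot itself be
minimal, so it is skipped without verification.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .attractors import _Engine, find_attractor
from .logic import LogicNetwork, check_clamps

__all__ = [
    "InterventionGoal",
    "InterventionSet",
    "intervention_valid",
    "enumerate_minimal_interventions",
    "intervention_target_frequencies",
]


@dataclasses.dataclass
class InterventionGoal:
    """Target state to enforce plus the experimental base clamps."""

    goal_node: str
    goal_value: int
    base_clamps: dict[str, int] = dataclasses.field(default_factory=dict)
    max_size: int = 3

    def __post_init__(self):
        if self.goal_value not in (0, 1):
            raise ValueError("goal_value must be 0 or 1")
        if self.goal_node in self.base_clamps:
            raise ValueError("goal node must not appear in the base clamps")
        if self.max_size < 1:
            raise ValueError("max_size must be >= 1")


@dataclasses.dataclass
class InterventionSet:
    """A verified minimal clamp set (base clamps excluded)."""

    clamps: dict[str, int]
    size: int
    valid: bool
    minimal: bool
    verified_mode: str  # "exhaustive" | "sampled"

    @property
    def members(self) -> str:
        return ";".join(f"{n}={v}" for n, v in sorted(self.clamps.items()))


def _verify_goal(
    network: LogicNetwork,
    clamps: Mapping[str, int],
    goal_node: str,
    goal_value: int,
    exhaustive_limit: int,
    n_samples: int | None,
    seed: int,
) -> tuple[bool, str]:
    """Goal holds in every attractor state reachable from the verified starts."""
    engine = _Engine(network, dict(clamps))
    goal_idx = engine.index[goal_node]
    if engine.n_free <= exhaustive_limit:
        succ = engine.successor_table()
        T = succ.copy()
        for _ in range(max(engine.n_free, 1)):
            T = T[T]
        on_cycle = np.unique(T)  # exactly the reachable cycle states
        X = engine.states_from_indices(on_cycle)
        return bool(np.all(X[:, goal_idx] == bool(goal_value))), "exhaustive"
    if not n_samples:
        raise ValueError(
            f"free state space 2^{engine.n_free} exceeds the exhaustive limit and "
            "no sampling verifier was configured"
        )
    rng = np.random.default_rng(seed)
    free_nodes = [network.nodes[i] for i in engine.free]
    for _ in range(n_samples):
        start = dict(clamps)
        bits = rng.integers(0, 2, size=len(free_nodes))
        start.update({node: int(b) for node, b in zip(free_nodes, bits)})
        att = find_attractor(network, start, clamps)
        if any(state[goal_node] != goal_value for state in att.states):
            return False, "sampled"
    return True, "sampled"


def intervention_valid(
    network: LogicNetwork,
    intervention: Mapping[str, int],
    goal: InterventionGoal,
    exhaustive_limit: int = 22,
    n_samples: int | None = 10_000,
    seed: int = 0,
) -> bool:
    """Check whether base clamps plus ``intervention`` enforce the goal in all
    reachable attractors."""
    intervention = check_clamps(network, intervention)
    if goal.goal_node in intervention:
        raise ValueError("intervention must not clamp the goal node itself")
    overlap = set(intervention) & set(goal.base_clamps)
    if overlap:
        raise ValueError(f"intervention overlaps base clamps: {sorted(overlap)}")
    merged = {**check_clamps(network, goal.base_clamps), **intervention}
    ok, _ = _verify_goal(
        network, merged, goal.goal_node, goal.goal_value, exhaustive_limit, n_samples, seed
    )
    return ok


def enumerate_minimal_interventions(
    network: LogicNetwork,
    goal: InterventionGoal,
    intervention_values: str = "both",
    exhaustive_limit: int = 22,
    n_samples: int | None = 10_000,
    seed: int = 0,
    candidate_nodes: Sequence[str] | None = None,
) -> list[InterventionSet]:
    """All minimal intervention sets of size <= ``goal.max_size``.

    ``intervention_values`` is ``"zero"`` for inhibitor-style clamps only or
    ``"both"`` to also search constitutive activations. Candidates default to
    every node except the goal and base-clamped nodes. Results are sorted by
    size then lexicographically; the search is deterministic.
    """
    if intervention_values not in ("both", "zero"):
        raise ValueError("intervention_values must be 'both' or 'zero'")
    values = (0, 1) if intervention_values == "both" else (0,)
    if candidate_nodes is None:
        candidate_nodes = [
            n for n in network.nodes if n != goal.goal_node and n not in goal.base_clamps
        ]
    else:
        bad = [n for n in candidate_nodes if n == goal.goal_node or n in goal.base_clamps]
        if bad:
            raise ValueError(f"candidates clash with goal/base clamps: {bad}")
    candidate_nodes = sorted(candidate_nodes)

    def verify(clamps: dict[str, int]) -> tuple[bool, str]:
        merged = {**check_clamps(network, goal.base_clamps), **clamps}
        return _verify_goal(
            network, merged, goal.goal_node, goal.goal_value,
            exhaustive_limit, n_samples, seed,
        )

    ok, mode = verify({})
    if ok:
        # goal already enforced by the base clamps alone: the empty set is the
        # unique minimal intervention
        return [InterventionSet({}, 0, True, True, mode)]

    found: list[InterventionSet] = []
    for size in range(1, goal.max_size + 1):
        for nodes in itertools.combinations(candidate_nodes, size):
            for assignment in itertools.product(values, repeat=size):
                clamps = dict(zip(nodes, assignment))
                items = set(clamps.items())
                if any(set(f.clamps.items()) <= items for f in found):
                    continue  # superset of a reported minimal set
                ok, mode = verify(clamps)
                if ok:
                    found.append(InterventionSet(clamps, size, True, True, mode))
    found.sort(key=lambda s: (s.size, sorted(s.clamps.items())))
    return found


def intervention_target_frequencies(
    sets: Sequence[InterventionSet],
    pathway_groups: Mapping[str, Sequence[str]] | None = None,
    size: int | None = None,
    network: LogicNetwork | None = None,
) -> dict:
    """Per-node occurrence counts/fractions across intervention sets, and the
    number of sets containing at least one member of each pathway group.

    ``size`` restricts the tally to sets of that size (e.g. three-target sets).
    """
    if not sets:
        raise ValueError("empty intervention-set list")
    selected = [s for s in sets if size is None or s.size == size]
    total = len(selected)
    node_counts: dict[str, int] = {}
    for s in selected:
        for node in s.clamps:
            node_counts[node] = node_counts.get(node, 0) + 1
    node_table = pd.DataFrame(
        {
            "count": pd.Series(node_counts, dtype=int),
            "fraction": pd.Series(
                {n: c / total for n, c in node_counts.items()} if total else {}
            ),
        }
    ).sort_values("count", ascending=False)

    group_counts: dict[str, int] = {}
    if pathway_groups:
        for label, members in pathway_groups.items():
            if network is not None:
                unknown = [m for m in members if m not in network.rules]
                if unknown:
                    raise KeyError(f"group {label!r} names unknown nodes: {unknown}")
            member_set = set(members)
            group_counts[label] = sum(
                1 for s in selected if member_set & set(s.clamps)
            )
    return {"n_sets": total, "nodes": node_table, "groups": group_counts}
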