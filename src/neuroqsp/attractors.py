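"""Synchronous attractor analysis and activation-frequency statistics.

Under the synchronous update a Boolean network is a deterministic map on a
finite state space, so every trajectory ends in an attractor: a fixed point or
a state cycle. The relative activation frequency of a node (``nu``) is its mean
activation over the attractors reached from many initial states — for each
start state the node contributes the mean of its value across the attractor's
cycle states (exactly its value for fixed points), and frequencies average
these contributions over all starts. ``nu`` for a designated goal node (e.g.
apoptosis) summarizes how often the network commits to that fate.

Two engines are used:

* networks whose free (unclamped) part has at most ``max_table_nodes`` nodes
  are analyzed through an explicit successor table over all ``2**n_free``
  states (bit-indexed, vectorized), which makes exhaustive enumeration and
  large sample counts cheap and exact;
* larger networks fall back to per-trajectory cycle detection on bit-packed
  integer states, with memoization of visited states so repeated basins are
  resolved in O(1) after first contact.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .logic import LogicNetwork, check_clamps, truth_table

__all__ = [
    "Attractor",
    "AttractorSample",
    "PanelResult",
    "find_attractor",
    "activation_frequencies",
    "perturbation_panel",
]

MAX_TABLE_NODES = 22          # successor table cap: 2^22 states
MAX_EXHAUSTIVE_NODES = 22     # spec'd exhaustive-enumeration cap
_CHUNK = 1 << 16


@dataclasses.dataclass
class Attractor:
    """A synchronous attractor in canonical rotation (lexicographically
    smallest packed state first)."""

    states: list[dict[str, int]]
    canonical_key: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.states)

    @property
    def is_fixed_point(self) -> bool:
        return len(self.states) == 1

    def node_mean(self, node: str) -> float:
        return float(np.mean([s[node] for s in self.states]))


@dataclasses.dataclass
class AttractorSample:
    """Activation frequencies over sampled (or exhausted) initial states."""

    n_samples: int
    seed: int | None
    clamps: dict[str, int]
    frequencies: dict[str, float]
    nu_goal: float | None
    attractor_census: dict[tuple[int, ...], int]
    mode: str                  # "exhaustive" | "sampled"
    cycle_stat: str            # "mean" | "first"
    goal: str | None = None


@dataclasses.dataclass
class PanelResult:
    """Multi-arm frequency panel in long format plus per-arm goal frequency."""

    table: pd.DataFrame        # columns: arm, node, frequency
    nu_goal: dict[str, float]
    samples: dict[str, AttractorSample]


class _Engine:
    """Bit-indexed synchronous stepper over the free-node state space."""

    def __init__(self, network: LogicNetwork, clamps: Mapping[str, int]):
        self.network = network
        self.nodes = network.nodes
        self.n = len(self.nodes)
        self.index = {node: i for i, node in enumerate(self.nodes)}
        self.clamps = dict(clamps)
        self.free = [i for i, node in enumerate(self.nodes) if node not in clamps]
        self.n_free = len(self.free)
        self.clamped_idx = np.array(
            [self.index[node] for node in clamps], dtype=int
        )
        self.clamped_val = np.array([clamps[node] for node in clamps], dtype=bool)
        self.rules = []
        for node in self.nodes:
            regs = network.regulators(node)
            reg_idx = np.array([self.index[r] for r in regs], dtype=int)
            self.rules.append((reg_idx, truth_table(network.rules[node], regs),
                               (1 << np.arange(len(regs))).astype(np.int64)))

    def step_matrix(self, X: np.ndarray) -> np.ndarray:
        """Synchronous update of a (S, n) boolean state matrix."""
        out = np.empty_like(X)
        for j, (reg_idx, table, weights) in enumerate(self.rules):
            if reg_idx.size:
                idx = X[:, reg_idx] @ weights
                out[:, j] = table[idx].astype(bool)
            else:
                out[:, j] = bool(table[0])
        if self.clamped_idx.size:
            out[:, self.clamped_idx] = self.clamped_val
        return out

    # free-state index <-> boolean state matrix
    def states_from_indices(self, idx: np.ndarray) -> np.ndarray:
        X = np.zeros((idx.size, self.n), dtype=bool)
        for j, node_i in enumerate(self.free):
            X[:, node_i] = (idx >> j) & 1
        if self.clamped_idx.size:
            X[:, self.clamped_idx] = self.clamped_val
        return X

    def indices_from_states(self, X: np.ndarray) -> np.ndarray:
        idx = np.zeros(X.shape[0], dtype=np.int64)
        for j, node_i in enumerate(self.free):
            idx |= X[:, node_i].astype(np.int64) << j
        return idx

    def successor_table(self) -> np.ndarray:
        """succ[i] = free-state index of the synchronous successor of state i."""
        N = 1 << self.n_free
        succ = np.empty(N, dtype=np.int64)
        for lo in range(0, N, _CHUNK):
            hi = min(lo + _CHUNK, N)
            block = np.arange(lo, hi, dtype=np.int64)
            succ[lo:hi] = self.indices_from_states(self.step_matrix(self.states_from_indices(block)))
        return succ

    def packed_full_state(self, X: np.ndarray) -> np.ndarray:
        """Pack complete node states (all nodes, node order) into integers."""
        out = np.zeros(X.shape[0], dtype=object)
        for i in range(self.n):
            out += X[:, i].astype(object) << i
        return out

    def state_dict(self, row: np.ndarray) -> dict[str, int]:
        return {node: int(row[i]) for i, node in enumerate(self.nodes)}


def _canonical_rotation(keys: list[int]) -> tuple[int, ...]:
    start = keys.index(min(keys))
    return tuple(keys[start:] + keys[:start])


def find_attractor(
    network: LogicNetwork,
    start: Mapping[str, int],
    clamps: Mapping[str, int] | None = None,
) -> Attractor:
    """Iterate the synchronous map from ``start`` until a state repeats;
    return the attractor cycle in canonical rotation."""
    clamps = check_clamps(network, clamps)
    engine = _Engine(network, clamps)
    x = np.array([[bool(start[node]) for node in network.nodes]])
    if engine.clamped_idx.size:
        x[:, engine.clamped_idx] = engine.clamped_val
    seen: dict[int, int] = {}
    history: list[np.ndarray] = []
    while True:
        key = int(engine.packed_full_state(x)[0])
        if key in seen:
            cycle_rows = history[seen[key]:]
            cycle_keys = [int(engine.packed_full_state(r[None, :])[0]) for r in cycle_rows]
            canon = _canonical_rotation(cycle_keys)
            offset = cycle_keys.index(canon[0])
            ordered = cycle_rows[offset:] + cycle_rows[:offset]
            return Attractor(
                states=[engine.state_dict(r) for r in ordered],
                canonical_key=canon,
            )
        seen[key] = len(history)
        history.append(x[0].copy())
        x = engine.step_matrix(x)


def _decompose_table(engine: _Engine, succ: np.ndarray):
    """Attractor decomposition of the successor table.

    Returns (att_of_state, cycles) where ``att_of_state[s]`` is the attractor id
    eventually reached from state ``s`` and ``cycles[a]`` is the list of
    free-state indices on cycle ``a``.
    """
    N = succ.size
    T = succ.copy()
    # pointer doubling: after n_free squarings T = succ^(2^n_free), 2^n_free >= N
    for _ in range(max(engine.n_free, 1)):
        T = T[T]
    on_cycle = np.unique(T)
    att_id = np.full(N, -1, dtype=np.int64)
    cycles: list[list[int]] = []
    for c in on_cycle:
        c = int(c)
        if att_id[c] != -1:
            continue
        cycle = [c]
        nxt = int(succ[c])
        while nxt != c:
            cycle.append(nxt)
            nxt = int(succ[nxt])
        cid = len(cycles)
        att_id[np.array(cycle, dtype=np.int64)] = cid
        cycles.append(cycle)
    return att_id[T], cycles


def _cycle_summaries(engine: _Engine, cycles: list[list[int]], cycle_stat: str):
    """Per-attractor node activation vector and canonical census key."""
    means = np.zeros((len(cycles), engine.n))
    keys: list[tuple[int, ...]] = []
    for a, cycle in enumerate(cycles):
        X = engine.states_from_indices(np.array(cycle, dtype=np.int64))
        packed = [int(v) for v in engine.packed_full_state(X)]
        canon = _canonical_rotation(packed)
        keys.append(canon)
        if cycle_stat == "first":
            means[a] = X[packed.index(canon[0])].astype(float)
        else:
            means[a] = X.mean(axis=0)
    return means, keys


def _frequencies_from_counts(engine, means, keys, counts):
    total = int(counts.sum())
    freq_vec = (counts[:, None] * means).sum(axis=0) / total
    census = {
        keys[a]: int(counts[a]) for a in np.nonzero(counts)[0]
    }
    freqs = {node: float(freq_vec[i]) for i, node in enumerate(engine.nodes)}
    return freqs, census


def activation_frequencies(
    network: LogicNetwork,
    clamps: Mapping[str, int] | None = None,
    n_samples: int = 10_000,
    seed: int | None = 0,
    goal: str | None = None,
    exhaustive: bool = False,
    cycle_stat: str = "mean",
    max_exhaustive_nodes: int = MAX_EXHAUSTIVE_NODES,
) -> AttractorSample:
    """Per-node relative activation frequencies over random (or all) start states.

    Start states are uniform over the free-node hypercube with clamped nodes
    fixed; ``exhaustive=True`` enumerates every free state exactly once.
    ``cycle_stat`` controls how cyclic attractors contribute: the per-node cycle
    mean (default) or the canonical first cycle state.
    """
    if cycle_stat not in ("mean", "first"):
        raise ValueError("cycle_stat must be 'mean' or 'first'")
    clamps = check_clamps(network, clamps)
    if goal is not None and goal not in network.rules:
        raise KeyError(f"goal node {goal!r} is not in the network")
    engine = _Engine(network, clamps)

    if exhaustive:
        if engine.n_free > max_exhaustive_nodes:
            raise ValueError(
                f"exhaustive enumeration requested for {engine.n_free} free nodes "
                f"(limit {max_exhaustive_nodes})"
            )
        att_of_state, cycles = _decompose_table(engine, engine.successor_table())
        means, keys = _cycle_summaries(engine, cycles, cycle_stat)
        counts = np.bincount(att_of_state, minlength=len(cycles))
        freqs, census = _frequencies_from_counts(engine, means, keys, counts)
        n_total = 1 << engine.n_free
        mode = "exhaustive"
    else:
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        rng = np.random.default_rng(seed)
        bits = rng.integers(0, 2, size=(n_samples, engine.n_free), dtype=np.int64)
        if engine.n_free <= MAX_TABLE_NODES:
            att_of_state, cycles = _decompose_table(engine, engine.successor_table())
            means, keys = _cycle_summaries(engine, cycles, cycle_stat)
            starts = bits @ (1 << np.arange(engine.n_free, dtype=np.int64))
            counts = np.bincount(att_of_state[starts], minlength=len(cycles))
            freqs, census = _frequencies_from_counts(engine, means, keys, counts)
        else:
            freqs, census = _sampled_large(engine, bits, cycle_stat)
        n_total = n_samples
        mode = "sampled"

    return AttractorSample(
        n_samples=n_total,
        seed=None if exhaustive else seed,
        clamps=dict(clamps),
        frequencies=freqs,
        nu_goal=None if goal is None else freqs[goal],
        attractor_census=census,
        mode=mode,
        cycle_stat=cycle_stat,
        goal=goal,
    )


def _sampled_large(engine: _Engine, all_bits: np.ndarray, cycle_stat: str):
    """Per-trajectory cycle detection with basin memoization for big networks."""
    basin_memo: dict[int, int] = {}     # packed full state -> attractor id
    att_means: list[np.ndarray] = []
    att_keys: list[tuple[int, ...]] = []
    key_to_id: dict[tuple[int, ...], int] = {}
    counts: list[int] = []

    for bits in all_bits.astype(bool):
        x = np.zeros((1, engine.n), dtype=bool)
        for j, node_i in enumerate(engine.free):
            x[0, node_i] = bits[j]
        if engine.clamped_idx.size:
            x[:, engine.clamped_idx] = engine.clamped_val
        path: list[int] = []
        pos: dict[int, int] = {}
        rows: list[np.ndarray] = []
        aid = None
        while True:
            key = int(engine.packed_full_state(x)[0])
            if key in basin_memo:
                aid = basin_memo[key]
                break
            if key in pos:
                cycle_rows = rows[pos[key]:]
                cycle_keys = path[pos[key]:]
                canon = _canonical_rotation(cycle_keys)
                if canon in key_to_id:
                    aid = key_to_id[canon]
                else:
                    X = np.array(cycle_rows)
                    if cycle_stat == "first":
                        mean = X[cycle_keys.index(canon[0])].astype(float)
                    else:
                        mean = X.mean(axis=0)
                    aid = len(att_means)
                    att_means.append(mean)
                    att_keys.append(canon)
                    key_to_id[canon] = aid
                    counts.append(0)
                break
            pos[key] = len(path)
            path.append(key)
            rows.append(x[0].copy())
            x = engine.step_matrix(x)
        for key in path:
            basin_memo[key] = aid
        counts[aid] += 1

    counts_arr = np.array(counts, dtype=np.int64)
    freqs, census = _frequencies_from_counts(engine, np.array(att_means), att_keys, counts_arr)
    return freqs, census


def perturbation_panel(
    network: LogicNetwork,
    arms: Sequence[tuple[str, Mapping[str, int]]],
    n_samples: int = 10_000,
    seed: int | None = 0,
    goal: str | None = None,
    exhaustive: bool = False,
    cycle_stat: str = "mean",
) -> PanelResult:
    """Activation-frequency panel across perturbation arms (label, clamps).

    Each arm gets an independent seed spawned from the shared base seed; the
    long-format table (arm, node, frequency) is ready for heatmap rendering.
    """
    if not arms:
        raise ValueError("at least one arm is required")
    labels = [label for label, _ in arms]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate arm labels: {labels}")
    arm_seeds = np.random.SeedSequence(seed).generate_state(len(arms)) % (2**31)
    samples: dict[str, AttractorSample] = {}
    records = []
    for (label, clamps), arm_seed in zip(arms, arm_seeds):
        sample = activation_frequencies(
            network,
            clamps=clamps,
            n_samples=n_samples,
            seed=int(arm_seed),
            goal=goal,
            exhaustive=exhaustive,
            cycle_stat=cycle_stat,
        )
        samples[label] = sample
        for node, freq in sample.frequencies.items():
            records.append({"arm": label, "node": node, "frequency": freq})
    table = pd.DataFrame.from_records(records)
    nu_goal = {label: s.nu_goal for label, s in samples.items()} if goal else {}
    return PanelResult(table=table, nu_goal=nu_goal, samples=samples)
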