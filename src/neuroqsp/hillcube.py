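"""Continuous simulation of Boolean networks via normalized HillCube ODEs.

Each Boolean rule is lifted to the unit hypercube by multilinear interpolation
of its truth table (the BooleCube), composed with a normalized Hill function
applied to every regulator:

    dx_i/dt = (1/tau) * ( B_i( h(x_r1), ..., h(x_rm) ) - x_i )

where ``h(x) = (x^n / (x^n + k^n)) / (1 / (1 + k^n))`` is the Hill curve
rescaled so h(1) = 1, B_i is the multilinear interpolation of rule i's truth
table, and tau sets the node's relaxation time. At every Boolean corner the
target value equals the discrete rule output, so discrete fixed points are
continuous equilibria.

Clamped nodes are held constant at the clamp value; unclamped input nodes
(self-rules) are held constant at their initial value, mirroring how inputs
are treated as experimental conditions rather than dynamical species.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .logic import Ast, LogicNetwork, check_clamps, expression_variables, parse_expression, truth_table

__all__ = [
    "HillCubeParams",
    "Trajectory",
    "normalized_hill",
    "boolecube",
    "simulate_hillcube",
    "binarize_state",
]

BOOLECUBE_MAX_REGULATORS = 12  # 2^m corner sum guard


@dataclasses.dataclass
class HillCubeParams:
    """Global HillCube shape parameters (defaults follow common qualitative use)."""

    tau: float = 1.0  # node relaxation time, arbitrary units
    k: float = 0.5    # Hill threshold, in (0, 1)
    n: float = 3.0    # Hill exponent

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0 < self.k < 1:
            raise ValueError("k must lie in (0, 1)")
        if self.n <= 0:
            raise ValueError("n must be positive")


@dataclasses.dataclass
class Trajectory:
    """Continuous trajectory on a fixed output grid."""

    times: np.ndarray
    states: pd.DataFrame          # index: time, columns: node names
    final: dict[str, float]
    steady_state: bool            # max |dx/dt| below tolerance at t_end
    max_final_derivative: float


def normalized_hill(x, n: float = 3.0, k: float = 0.5):
    """Hill curve rescaled so that h(0) = 0 and h(1) = 1; strictly increasing."""
    x = np.asarray(x, dtype=float)
    if np.any(x < -1e-12) or np.any(x > 1 + 1e-12):
        raise ValueError("normalized_hill input must lie in [0, 1]")
    x = np.clip(x, 0.0, 1.0)
    xn = x ** n
    val = xn / (xn + k ** n) * (1.0 + k ** n)
    return val if val.shape else float(val)


def _corner_bits(m: int) -> np.ndarray:
    corners = np.arange(1 << m)[:, None]
    return ((corners >> np.arange(m)[None, :]) & 1).astype(bool)


def boolecube(rule: str | Ast, xbar: Sequence[float], regulators: Sequence[str] | None = None) -> float:
    """Multilinear interpolation of a Boolean rule's truth table.

    ``xbar`` gives the continuous activity of each regulator (first-appearance
    order of the rule unless ``regulators`` is passed). At Boolean corners the
    value equals the discrete rule output.
    """
    ast = parse_expression(rule) if isinstance(rule, str) else rule
    regs = list(regulators) if regulators is not None else expression_variables(ast)
    m = len(regs)
    if m > BOOLECUBE_MAX_REGULATORS:
        raise ValueError(f"rule has {m} regulators; limit is {BOOLECUBE_MAX_REGULATORS}")
    xbar = np.asarray(xbar, dtype=float)
    if xbar.shape != (m,):
        raise ValueError(f"expected {m} regulator activities, got shape {xbar.shape}")
    if np.any(xbar < -1e-12) or np.any(xbar > 1 + 1e-12):
        raise ValueError("regulator activities must lie in [0, 1]")
    xbar = np.clip(xbar, 0.0, 1.0)
    table = truth_table(ast, regs).astype(float)
    bits = _corner_bits(m)
    weights = np.prod(np.where(bits, xbar, 1.0 - xbar), axis=1)
    return float(table @ weights)


class _CompiledHillCube:
    """Precompiled RHS: per-node truth table + corner bit matrix."""

    def __init__(self, network: LogicNetwork, clamps: Mapping[str, int], params: HillCubeParams):
        self.network = network
        self.params = params
        self.index = {node: i for i, node in enumerate(network.nodes)}
        self.frozen = np.zeros(len(network.nodes), dtype=bool)
        self.dynamic: list[tuple[int, np.ndarray, np.ndarray, np.ndarray]] = []
        for node in network.nodes:
            i = self.index[node]
            if node in clamps or network.is_input(node):
                self.frozen[i] = True
                continue
            regs = network.regulators(node)
            if len(regs) > BOOLECUBE_MAX_REGULATORS:
                raise ValueError(
                    f"node {node!r} has {len(regs)} regulators; limit is {BOOLECUBE_MAX_REGULATORS}"
                )
            table = truth_table(network.rules[node], regs).astype(float)
            reg_idx = np.array([self.index[r] for r in regs], dtype=int)
            self.dynamic.append((i, reg_idx, table, _corner_bits(len(regs))))

    def rhs(self, t, x):
        p = self.params
        h = normalized_hill(np.clip(x, 0.0, 1.0), p.n, p.k)
        dx = np.zeros_like(x)
        for i, reg_idx, table, bits in self.dynamic:
            hr = h[reg_idx]
            weights = np.prod(np.where(bits, hr, 1.0 - hr), axis=1)
            dx[i] = (table @ weights - x[i]) / p.tau
        return dx


def simulate_hillcube(
    network: LogicNetwork,
    x0: Mapping[str, float],
    clamps: Mapping[str, int] | None = None,
    params: HillCubeParams | None = None,
    t_end: float = 25.0,
    n_out: int = 101,
    steady_tol: float = 1e-6,
) -> Trajectory:
    """Integrate the HillCube ODEs on [0, t_end] and sample ``n_out`` even time points.

    ``x0`` must assign every node an activity in [0, 1]; clamped nodes are
    overridden by their clamp value and held there.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    params = params or HillCubeParams()
    clamps = check_clamps(network, clamps)
    missing = [n for n in network.nodes if n not in x0]
    if missing:
        raise KeyError(f"x0 is missing nodes: {missing}")

    x_init = np.array([float(x0[n]) for n in network.nodes])
    if np.any(x_init < 0) or np.any(x_init > 1):
        raise ValueError("initial activities must lie in [0, 1]")
    for node, value in clamps.items():
        x_init[network.nodes.index(node)] = float(value)

    compiled = _CompiledHillCube(network, clamps, params)
    times = np.linspace(0.0, t_end, n_out)
    sol = solve_ivp(
        compiled.rhs,
        (0.0, t_end),
        x_init,
        method="LSODA",
        t_eval=times,
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        worst = int(np.argmax(np.abs(compiled.rhs(sol.t[-1], sol.y[:, -1]))))
        raise RuntimeError(
            f"integration failed: {sol.message} (largest residual at node "
            f"{network.nodes[worst]!r})"
        )
    values = np.clip(sol.y.T, 0.0, 1.0)
    states = pd.DataFrame(values, index=times, columns=network.nodes)
    states.index.name = "time"
    final = {node: float(values[-1, i]) for i, node in enumerate(network.nodes)}
    max_deriv = float(np.max(np.abs(compiled.rhs(t_end, values[-1]))))
    return Trajectory(
        times=times,
        states=states,
        final=final,
        steady_state=max_deriv < steady_tol,
        max_final_derivative=max_deriv,
    )


def binarize_state(
    values: Mapping[str, float], band: tuple[float, float] = (0.45, 0.55)
) -> dict[str, int | None]:
    """Threshold continuous activities at 0.5 with an indeterminate tie band.

    Returns 1 (ON) above the band, 0 (OFF) below it, and None inside it.
    """
    lo, hi = band
    out: dict[str, int | None] = {}
    for node, v in values.items():
        if lo <= v <= hi:
            out[node] = None
        else:
            out[node] = 1 if v > 0.5 else 0
    return out
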