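"""Direction-of-change qualification of network predictions against
differential-expression tables.

A perturbation (e.g. a gene knockout plus an agonist, encoded as clamps) is
simulated to steady state with the HillCube ODEs; each unclamped node's final
activity is binarized and reported as *increasing* when it ends ON, and
*decreasing* when it ends OFF — the direction is defined by the final state
alone. Predictions are then compared with the sign of the log2 fold-change of
the matching genes in a probe-level differential-expression table: a node
agrees when an increasing call meets log2fc > 0 or a decreasing call meets
log2fc < 0. Multi-probe genes are collapsed first, either by keeping the probe
with the smallest adjusted p-value or by averaging log2 fold-changes.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hillcube import HillCubeParams, binarize_state, simulate_hillcube
from .logic import LogicNetwork, check_clamps

__all__ = [
    "DirectionCall",
    "predict_node_directions",
    "collapse_probes",
    "direction_agreement",
]

DE_COLUMNS = ("probe_id", "gene_symbol", "log2fc", "adj_p")


@dataclasses.dataclass
class DirectionCall:
    """Predicted direction of change for one node under a perturbation."""

    node: str
    initial: float
    final: float
    call: str                     # "increasing" | "decreasing" | "indeterminate"
    no_change_from_initial: bool  # final binarizes to the (binary) initial value
    converged: bool = True


def predict_node_directions(
    network: LogicNetwork,
    clamps: Mapping[str, int],
    x0: Mapping[str, float] | None = None,
    params: HillCubeParams | None = None,
    t_end: float = 25.0,
    band: tuple[float, float] = (0.45, 0.55),
) -> list[DirectionCall]:
    """Simulate to steady state under ``clamps`` and call each unclamped node's
    direction from its binarized final activity.

    ``x0`` defaults to the network's stored initial state, else all nodes OFF.
    Non-convergence by ``t_end`` still emits calls, flagged ``converged=False``.
    """
    clamps = check_clamps(network, clamps)
    if x0 is None:
        x0 = network.initial_state or {n: 0.0 for n in network.nodes}
        x0 = {n: float(x0.get(n, 0.0)) for n in network.nodes}
    traj = simulate_hillcube(network, x0, clamps=clamps, params=params, t_end=t_end)
    binary = binarize_state(traj.final, band=band)
    calls = []
    for node in network.nodes:
        if node in clamps:
            continue
        b = binary[node]
        if b is None:
            call = "indeterminate"
            no_change = False
        else:
            call = "increasing" if b == 1 else "decreasing"
            no_change = int(round(float(x0[node]))) == b
        calls.append(
            DirectionCall(
                node=node,
                initial=float(x0[node]),
                final=traj.final[node],
                call=call,
                no_change_from_initial=no_change,
                converged=traj.steady_state,
            )
        )
    return calls


def collapse_probes(table: pd.DataFrame, mode: str = "min_adj_p") -> pd.DataFrame:
    """Collapse a probe-level table to one row per gene.

    ``min_adj_p`` keeps the probe with the smallest adjusted p-value (ties:
    largest |log2fc|, then first occurrence); ``mean_log2fc`` averages log2
    fold-changes and keeps the smallest adjusted p-value. Probes with missing
    log2fc are dropped with a warning.
    """
    if mode not in ("min_adj_p", "mean_log2fc"):
        raise ValueError("mode must be 'min_adj_p' or 'mean_log2fc'")
    missing = [c for c in DE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"DE table lacks columns: {missing}")
    if table.empty:
        raise ValueError("empty DE table")
    table = table.copy()
    n_bad = int(table["log2fc"].isna().sum())
    if n_bad:
        warnings.warn(f"dropping {n_bad} probes with missing log2fc")
        table = table.dropna(subset=["log2fc"])

    if mode == "min_adj_p":
        table["_order"] = np.arange(len(table))
        table["_abs"] = table["log2fc"].abs()
        table = table.sort_values(
            ["gene_symbol", "adj_p", "_abs", "_order"],
            ascending=[True, True, False, True],
        )
        out = table.groupby("gene_symbol", sort=True).first().reset_index()
        return out[["gene_symbol", "probe_id", "log2fc", "adj_p"]]
    out = (
        table.groupby("gene_symbol", sort=True)
        .agg(log2fc=("log2fc", "mean"), adj_p=("adj_p", "min"), n_probes=("probe_id", "size"))
        .reset_index()
    )
    return out


def direction_agreement(
    calls: Sequence[DirectionCall],
    genes: pd.DataFrame,
    node_gene_map: Mapping[str, str],
) -> dict:
    """Compare directional calls with gene-level log2 fold-changes.

    Indeterminate calls are listed but excluded from the denominator; a log2fc
    of exactly 0 disagrees with any directional call. Returns the per-node
    table, agreement fraction, and counts.
    """
    if "gene_symbol" not in genes.columns or "log2fc" not in genes.columns:
        raise ValueError("gene table needs gene_symbol and log2fc columns")
    lfc_by_gene = genes.set_index("gene_symbol")["log2fc"].to_dict()
    rows = []
    indeterminate = []
    for call in calls:
        gene = node_gene_map.get(call.node)
        if gene is None or gene not in lfc_by_gene:
            continue
        lfc = float(lfc_by_gene[gene])
        if call.call == "indeterminate":
            indeterminate.append(call.node)
            rows.append(
                {"node": call.node, "gene_symbol": gene, "call": call.call,
                 "log2fc": lfc, "agree": None,
                 "no_change_from_initial": call.no_change_from_initial}
            )
            continue
        agree = (call.call == "increasing" and lfc > 0) or (
            call.call == "decreasing" and lfc < 0
        )
        rows.append(
            {"node": call.node, "gene_symbol": gene, "call": call.call,
             "log2fc": lfc, "agree": bool(agree),
             "no_change_from_initial": call.no_change_from_initial}
        )
    if not rows:
        raise ValueError("no network node maps to a gene present in the table")
    table = pd.DataFrame(rows)
    scored = table[table["agree"].notna()]
    n_total = len(scored)
    n_agree = int(scored["agree"].sum()) if n_total else 0
    return {
        "table": table,
        "n_agree": n_agree,
        "n_total": n_total,
        "fraction": (n_agree / n_total) if n_total else float("nan"),
        "indeterminate_nodes": indeterminate,
    }
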