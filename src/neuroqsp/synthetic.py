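"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator is a pure function of its arguments (seed included) and returns
its output together with a ground-truth dictionary sufficient to score any
downstream estimate. Defaults encode the study conditions the analyses are
designed around: a checkerboard viability plate spanning the bortezomib IC50,
biexponential dexanabinol plasma profiles in rat and human anchored to ~4 h
terminal half-lives, and a four-arm mouse tumor study (control / dexanabinol /
bortezomib / combination) with twice-weekly dosing, proportional measurement
error, resistance onset k_res = 0.0076 1/h and interaction psi_viv = 0.883.
"""

from __future__ import annotations

import importlib.resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .logic import Ast, LogicNetwork, parse_bnet
from .pkpd import (
    ConcentrationProfile,
    HillParams,
    InteractionParams,
    TumorPDParams,
    TwoCompartmentParams,
    ariens_combined_viability,
    hill_viability,
    simulate_tumor_model,
    two_compartment_profile,
)
from .qualification import DirectionCall

__all__ = [
    "generate_random_network",
    "toy_cipn_network",
    "generate_viability_plate",
    "generate_pk_profiles",
    "generate_tumor_study",
    "generate_de_table",
    "DEX_RAT_PK",
    "DEX_HUMAN_PK",
    "RAT_BW_KG",
    "HUMAN_BW_KG",
    "MOUSE_BW_KG",
    "DEFAULT_TUMOR_PARAMS",
]

# --------------------------------------------------------------------------- #
# networks

def _sop_ast(regulators: Sequence[str], table: np.ndarray) -> Ast:
    """Sum-of-products AST realizing a truth table over the given regulators."""
    if not table.any():
        return ("const", 0)
    if table.all():
        return ("const", 1)
    minterms = []
    m = len(regulators)
    for corner in np.nonzero(table)[0]:
        literals = []
        for j in range(m):
            var: Ast = ("var", regulators[j])
            literals.append(var if (corner >> j) & 1 else ("not", var))
        term = literals[0]
        for lit in literals[1:]:
            term = ("and", term, lit)
        minterms.append(term)
    expr = minterms[0]
    for term in minterms[1:]:
        expr = ("or", expr, term)
    return expr


def generate_random_network(N: int, K: int, seed: int) -> LogicNetwork:
    """Random Boolean network: each node gets 1..K distinct regulators and a
    uniformly random truth table (expressed as a sum of products)."""
    if N < 2:
        raise ValueError("N must be >= 2")
    if not 1 <= K <= N:
        raise ValueError("K must lie in 1..N")
    rng = np.random.default_rng(seed)
    nodes = [f"N{i}" for i in range(N)]
    rules: dict[str, Ast] = {}
    for node in nodes:
        k = int(rng.integers(1, K + 1))
        regs = [nodes[i] for i in rng.choice(N, size=k, replace=False)]
        table = rng.integers(0, 2, size=1 << k).astype(np.uint8)
        rules[node] = _sop_ast(regs, table)
    return LogicNetwork(nodes, rules)


def toy_cipn_network() -> LogicNetwork:
    """The bundled toy proteasome-inhibitor neurotoxicity fixture network."""
    text = (
        importlib.resources.files("neuroqsp").joinpath("data/toy_cipn.bnet").read_text()
    )
    return parse_bnet(text)


def full_cipn_network() -> LogicNetwork:
    """The complete 131-node neuronal signaling model (not bundled).

    The full model is distributed in the supplementary material of its source
    publication and must be transcribed once into the ``.bnet`` dialect and
    placed at ``data/full_cipn_model.bnet`` inside the package; this loader
    then makes every analysis in the package available at full scale. Raises
    ``FileNotFoundError`` when the transcription is absent.
    """
    resource = importlib.resources.files("neuroqsp").joinpath("data/full_cipn_model.bnet")
    if not resource.is_file():
        raise FileNotFoundError(
            "full_cipn_model.bnet is not bundled: the 131-node model listing is "
            "only available in its publication's supplementary material and must "
            "be transcribed to the .bnet dialect (see toy_cipn.bnet for the format)"
        )
    return parse_bnet(resource.read_text())


def reference_dexanabinol_pk() -> dict[str, tuple[float, TwoCompartmentParams]]:
    """Published rat/human dexanabinol two-compartment estimates (not bundled).

    The fitted parameter tables appear only in the source publication's
    supplementary material; when a transcription is placed at
    ``data/dexanabinol_pk_reference.json`` (mapping species to body weight and
    CL/V1/Q/V2), this loader feeds the allometric mouse prediction. Raises
    ``FileNotFoundError`` otherwise. The synthetic two-species workflow in
    :func:`generate_pk_profiles` is the self-contained substitute.
    """
    resource = importlib.resources.files("neuroqsp").joinpath(
        "data/dexanabinol_pk_reference.json"
    )
    if not resource.is_file():
        raise FileNotFoundError(
            "dexanabinol_pk_reference.json is not bundled: the fitted rat/human "
            "parameter tables are only in the publication's supplementary material"
        )
    import json

    raw = json.loads(resource.read_text())
    return {
        species: (entry["BW"], TwoCompartmentParams(**entry["params"]))
        for species, entry in raw.items()
    }


# --------------------------------------------------------------------------- #
# viability plates

DEFAULT_BORT_GRID_NM = (0.0, 0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)
DEFAULT_DEX_GRID_UM = (0.0, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0)
DEFAULT_BORT_HILL = HillParams(V0=100.0, Imax=1.0, IC50=1.5, gamma=1.0)   # nM
DEFAULT_DEX_HILL = HillParams(V0=100.0, Imax=1.0, IC50=19.0, gamma=1.0)   # uM


def _cv_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


def generate_viability_plate(
    p_B: HillParams = DEFAULT_BORT_HILL,
    p_D: HillParams = DEFAULT_DEX_HILL,
    psi: float | InteractionParams = 2.10,
    b_grid: Sequence[float] = DEFAULT_BORT_GRID_NM,
    d_grid: Sequence[float] = DEFAULT_DEX_GRID_UM,
    reps: int = 3,
    cv: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Checkerboard viability plate with multiplicative noise.

    Single-agent wells follow the plain inhibitory Hill curves (the
    interaction only acts when both drugs are present); combination wells
    follow the combined-viability model with the given psi. Returns
    (plate, ground_truth)."""
    rng = np.random.default_rng(seed)
    rows = []
    for cb in b_grid:
        for cd in d_grid:
            if cb > 0 and cd > 0:
                mean = ariens_combined_viability(cb, cd, p_B, p_D, psi)
            elif cb > 0:
                mean = hill_viability(cb, p_B)
            elif cd > 0:
                mean = hill_viability(cd, p_D)
            else:
                mean = p_B.V0
            for rep in range(1, reps + 1):
                rows.append(
                    {"drug_b_conc": cb, "drug_d_conc": cd, "replicate": rep,
                     "viability_pct": mean}
                )
    plate = pd.DataFrame(rows)
    plate["viability_pct"] *= _cv_factors(rng, cv, len(plate))
    psi_val = psi.psi_vit if isinstance(psi, InteractionParams) else float(psi)
    truth = {
        "p_B": p_B, "p_D": p_D, "psi_vit": psi_val, "cv": cv, "seed": seed,
    }
    return plate, truth


# --------------------------------------------------------------------------- #
# pharmacokinetics

RAT_BW_KG = 0.25
HUMAN_BW_KG = 70.0
MOUSE_BW_KG = 0.02

# Dexanabinol-like two-compartment parameters (volumes L, clearances L/h),
# chosen so the terminal half-life is ~4.0 h in rat and ~4.3 h in human,
# matching the reported near-species-independent disposition.
DEX_RAT_PK = TwoCompartmentParams(CL=0.06, V1=0.1, Q=0.04, V2=0.12)
DEX_HUMAN_PK = TwoCompartmentParams(CL=25.0, V1=30.0, Q=30.0, V2=75.0)

DEFAULT_PK_TIMES_H = (0.083, 0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0)


def generate_pk_profiles(
    species: Mapping[str, tuple[float, TwoCompartmentParams, Sequence]] | None = None,
    times: Sequence[float] = DEFAULT_PK_TIMES_H,
    cv: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Plasma concentration tables for two (or more) species.

    ``species`` maps name -> (body weight kg, parameters, dose list); defaults
    to rat and human single IV bolus doses of 10 mg/kg equivalents. Returns a
    long table (species, time_h, conc) plus ground truth.
    """
    if species is None:
        species = {
            "rat": (RAT_BW_KG, DEX_RAT_PK, [(0.0, 2.5, "iv")]),
            "human": (HUMAN_BW_KG, DEX_HUMAN_PK, [(0.0, 700.0, "iv")]),
        }
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    rows = []
    for name, (bw, params, doses) in species.items():
        conc = two_compartment_profile(params, doses)(times)
        conc = conc * _cv_factors(rng, cv, times.size)
        for t, c in zip(times, conc):
            rows.append({"species": name, "time_h": t, "conc": c})
    truth = {
        name: {"BW": bw, "params": params, "doses": list(doses)}
        for name, (bw, params, doses) in species.items()
    }
    truth["cv"] = cv
    truth["seed"] = seed
    return pd.DataFrame(rows), truth


# --------------------------------------------------------------------------- #
# tumor studies

# Mouse forcing-function surrogates (amounts in umol, volumes L, rates 1/h):
# bortezomib 1 mg/kg IP twice weekly, dexanabinol 10 mg/kg IP twice weekly.
BORT_MOUSE_PK = TwoCompartmentParams(CL=0.0035, V1=0.025, Q=0.005, V2=0.1, ka=2.0)
DEX_MOUSE_PK = TwoCompartmentParams(
    CL=0.004018, V1=0.007762, Q=0.002058, V2=0.006698, ka=2.0
)
BORT_DOSE_UMOL = 0.052
DEX_DOSE_UMOL = 0.518
BORT_DOSE_TIMES_H = (0.0, 96.0, 168.0, 264.0, 336.0, 432.0)   # days 1,5,8,12,15,19
DEX_DOSE_TIMES_H = (0.0, 96.0, 168.0, 264.0, 336.0)           # days 1,5,8,12,15
DEFAULT_TUMOR_TIMES_H = (0.0, 72.0, 168.0, 240.0, 336.0, 408.0, 504.0, 576.0, 672.0)

DEFAULT_TUMOR_PARAMS = TumorPDParams(
    TV0=100.0,      # mm^3 at treatment start
    kg0=0.006,      # 1/h
    kgr=0.002,      # 1/h
    K_bort=0.05,    # 1/(uM*h)
    K_dex=0.0002,   # 1/(uM*h)
    k_res=0.0076,   # 1/h
    psi_viv=0.883,
)


def default_tumor_concentrations() -> dict[str, tuple]:
    """Per-arm (C_bort, C_dex) forcing functions for the default study design."""
    c_bort = two_compartment_profile(
        BORT_MOUSE_PK, [(t, BORT_DOSE_UMOL, "extravascular") for t in BORT_DOSE_TIMES_H]
    )
    c_dex = two_compartment_profile(
        DEX_MOUSE_PK, [(t, DEX_DOSE_UMOL, "extravascular") for t in DEX_DOSE_TIMES_H]
    )
    return {
        "control": (None, None),
        "dex": (None, c_dex),
        "bort": (c_bort, None),
        "combo": (c_bort, c_dex),
    }


def generate_tumor_study(
    params: TumorPDParams = DEFAULT_TUMOR_PARAMS,
    n_per_arm: int = 5,
    times: Sequence[float] = DEFAULT_TUMOR_TIMES_H,
    cv: float = 0.10,
    seed: int = 0,
    concentrations: Mapping[str, tuple] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Four-arm tumor-volume study with proportional measurement error.

    Monotherapy arms are simulated with psi = 1 (no interaction partner); the
    combination arm uses ``params.psi_viv``. Returns (study table, truth); the
    truth dict carries the forcing functions needed to refit.
    """
    if concentrations is None:
        concentrations = default_tumor_concentrations()
    if "control" not in concentrations:
        raise ValueError("study design must include a control arm")
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    rows = []
    for arm, (c_b, c_d) in concentrations.items():
        psi = params.psi_viv if (c_b is not None and c_d is not None) else 1.0
        mean = simulate_tumor_model(params, times, c_bort=c_b, c_dex=c_d, psi=psi)
        for animal in range(1, n_per_arm + 1):
            noisy = mean * _cv_factors(rng, cv, times.size)
            for t, tv in zip(times, noisy):
                rows.append(
                    {"arm": arm, "animal_id": f"{arm}_{animal:02d}",
                     "time_h": t, "tv_mm3": tv}
                )
    truth = {
        "params": params, "cv": cv, "seed": seed,
        "concentrations": dict(concentrations),
    }
    return pd.DataFrame(rows), truth


# --------------------------------------------------------------------------- #
# differential expression

def generate_de_table(
    calls: Sequence[DirectionCall],
    discordance: float = 0.0,
    lfc_scale: float = 1.0,
    seed: int = 0,
    node_gene_map: Mapping[str, str] | None = None,
    max_probes: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """Probe-level differential-expression table consistent with directional
    calls, with each gene's sign flipped independently at the given
    discordance rate.

    Genes get 1..max_probes probes sharing the log2fc sign; the designated best
    probe carries the smallest adjusted p-value. Indeterminate calls are
    skipped. Returns (table, truth) where truth records which genes were
    flipped.
    """
    if not 0 <= discordance <= 1:
        raise ValueError("discordance must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    node_gene_map = dict(node_gene_map) if node_gene_map else {
        c.node: c.node.upper() for c in calls
    }
    rows = []
    flipped: list[str] = []
    for call in calls:
        if call.call == "indeterminate":
            continue
        gene = node_gene_map[call.node]
        sign = 1.0 if call.call == "increasing" else -1.0
        if rng.random() < discordance:
            sign = -sign
            flipped.append(gene)
        n_probes = int(rng.integers(1, max_probes + 1))
        best = int(rng.integers(0, n_probes))
        for i in range(n_probes):
            magnitude = max(abs(rng.normal(0.0, lfc_scale)), 0.05)
            adj_p = (
                rng.uniform(1e-6, 0.01) if i == best else rng.uniform(0.011, 0.05)
            )
            rows.append(
                {"probe_id": f"{gene}_p{i + 1}", "gene_symbol": gene,
                 "log2fc": sign * magnitude, "adj_p": adj_p}
            )
    table = pd.DataFrame(rows)
    truth = {
        "discordance": discordance, "seed": seed, "flipped_genes": flipped,
        "node_gene_map": node_gene_map,
    }
    return table, truth
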