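"""PK/PD models for the bortezomib + dexanabinol interaction studies.

In vitro: single-agent cytotoxicity follows an inhibitory Hill function of
concentration; two-drug viability uses a competitive (modified Ariens)
combination in which an interaction multiplier ``psi_vit`` scales the
bortezomib IC50 inside the shared denominator (psi < 1 synergy, = 1 additive,
> 1 antagonism), and Bliss independence classifies observed combination
effects. Estimation is staged: single-agent parameters are fit first and held
fixed while ``psi_vit`` is estimated from combination wells.

In vivo: dexanabinol disposition is a linear two-compartment model; parameters
are translated across species by per-parameter power laws ``X = alpha*BW^beta``
solved exactly from two species. Tumor growth under treatment follows

    dkg/dt = -kgr * kg,        kg(0) = kg0
    dTV/dt = kg(t)*TV - K_Dex*C_Dex*TV - K_Bort*exp(-psi_viv*k_res*t)*C_Bort*TV

i.e. exponential growth with a decaying rate constant, second-order drug kill,
an exponential onset of bortezomib resistance (``k_res``), and an interaction
multiplier ``psi_viv`` on the resistance rate (psi_viv < 1: the partner drug
slows resistance onset, a synergistic interaction). The no-drug solution is
the closed form ``TV0*exp[(kg0/kgr)(1 - e^(-kgr t))]``.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "HillParams",
    "InteractionParams",
    "TwoCompartmentParams",
    "AllometricCoefficients",
    "TumorPDParams",
    "TumorFitResult",
    "ConcentrationProfile",
    "hill_viability",
    "ariens_combined_viability",
    "bliss_classification",
    "fit_single_agent",
    "fit_interaction_psi",
    "two_compartment_profile",
    "simulate_two_compartment",
    "terminal_half_life",
    "fit_two_compartment",
    "solve_allometry",
    "tumor_growth_closed_form",
    "simulate_tumor_model",
    "fit_tumor_study",
]


# --------------------------------------------------------------------------- #
# in vitro viability

@dataclasses.dataclass
class HillParams:
    """Inhibitory Hill (Emax) parameters for one drug."""

    V0: float          # baseline viability, %
    Imax: float        # maximal fractional inhibition, (0, 1]
    IC50: float        # half-maximal concentration
    gamma: float = 1.0 # Hill slope

    def __post_init__(self):
        if self.V0 <= 0 or self.IC50 <= 0 or self.gamma <= 0:
            raise ValueError("V0, IC50 and gamma must be positive")
        if not 0 < self.Imax <= 1:
            raise ValueError("Imax must lie in (0, 1]")


@dataclasses.dataclass
class InteractionParams:
    """Multiplier on the bortezomib IC50 in the combined-viability model."""

    psi_vit: float

    def __post_init__(self):
        if self.psi_vit <= 0:
            raise ValueError("psi_vit must be positive")

    @property
    def interpretation(self) -> str:
        if self.psi_vit < 1:
            return "synergy"
        if self.psi_vit > 1:
            return "antagonism"
        return "additive"


def hill_viability(C, p: HillParams):
    """Viability (%) at concentration C: ``V0*(1 - Imax*C^g/(IC50^g + C^g))``."""
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentrations must be non-negative")
    Cg = C ** p.gamma
    v = p.V0 * (1.0 - p.Imax * Cg / (p.IC50 ** p.gamma + Cg))
    return v if v.shape else float(v)


def ariens_combined_viability(
    C_B, C_D, p_B: HillParams, p_D: HillParams, psi: InteractionParams | float
):
    """Two-drug viability with a shared competitive denominator.

    ``V0*(1 - (Imax_B*r_B + Imax_D*r_D)/(1 + r_B + r_D))`` with
    ``r_B = (C_B/(psi*IC50_B))^gB`` and ``r_D = (C_D/IC50_D)^gD``; reduces to
    the single-agent Hill curve when the other drug is absent and psi = 1.
    """
    psi_val = psi.psi_vit if isinstance(psi, InteractionParams) else float(psi)
    if psi_val <= 0:
        raise ValueError("psi must be positive")
    C_B = np.asarray(C_B, dtype=float)
    C_D = np.asarray(C_D, dtype=float)
    if np.any(C_B < 0) or np.any(C_D < 0):
        raise ValueError("concentrations must be non-negative")
    r_B = (C_B / (psi_val * p_B.IC50)) ** p_B.gamma
    r_D = (C_D / p_D.IC50) ** p_D.gamma
    v = p_B.V0 * (1.0 - (p_B.Imax * r_B + p_D.Imax * r_D) / (1.0 + r_B + r_D))
    return v if v.shape else float(v)


def bliss_classification(fa: float, fb: float, fab_obs: float, tol: float = 0.05) -> dict:
    """Bliss independence: expected combined inhibition ``fa + fb - fa*fb``.

    The excess ``fab_obs - expected`` is labelled synergy (> tol), antagonism
    (< -tol) or additive within the tolerance band.
    """
    for name, f in (("fa", fa), ("fb", fb), ("fab_obs", fab_obs)):
        if not 0 <= f <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {f}")
    expected = fa + fb - fa * fb
    excess = fab_obs - expected
    if excess > tol:
        label = "synergy"
    elif excess < -tol:
        label = "antagonism"
    else:
        label = "additive"
    return {"expected": expected, "excess": excess, "label": label}


def fit_single_agent(
    plate: pd.DataFrame,
    conc_col: str = "conc",
    viability_col: str = "viability_pct",
    fit_gamma: bool = False,
) -> tuple[HillParams, dict]:
    """Weighted least-squares fit of the inhibitory Hill model to one drug's plate.

    Weights are proportional to the observed viability (constant-CV error).
    Returns the parameter estimates and a diagnostics dict with standard
    errors, residuals, and a ``flat_response`` flag when Imax collapses toward
    zero (e.g. non-decreasing input data).
    """
    conc = plate[conc_col].to_numpy(dtype=float)
    via = plate[viability_col].to_numpy(dtype=float)
    if len(np.unique(conc)) < 4:
        raise ValueError("need at least 4 distinct concentrations")

    v0_start = float(np.mean(via[conc == conc.min()]))
    imax_start = float(np.clip(1.0 - via[conc == conc.max()].mean() / max(v0_start, 1e-9), 0.05, 0.999))
    positive = conc[conc > 0]
    ic50_start = float(np.exp(np.median(np.log(positive)))) if positive.size else 1.0
    p0 = [v0_start, imax_start, math.log(ic50_start)]
    lower = [1e-6, 1e-6, math.log(1e-12)]
    upper = [np.inf, 1.0, math.log(1e12)]
    if fit_gamma:
        p0.append(1.0)
        lower.append(0.1)
        upper.append(10.0)

    def model(C, V0, Imax, log_ic50, gamma=1.0):
        return hill_viability(C, HillParams(V0, Imax, math.exp(log_ic50), gamma))

    sigma = np.maximum(via, 1.0)
    try:
        popt, pcov = optimize.curve_fit(
            model, conc, via, p0=p0, sigma=sigma, absolute_sigma=False,
            bounds=(lower, upper), maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"Hill fit did not converge (start values V0={v0_start:.3g}, "
            f"Imax={imax_start:.3g}, IC50={ic50_start:.3g}): {err}"
        ) from None
    se = np.sqrt(np.diag(pcov))
    params = HillParams(
        V0=float(popt[0]),
        Imax=float(popt[1]),
        IC50=float(math.exp(popt[2])),
        gamma=float(popt[3]) if fit_gamma else 1.0,
    )
    residuals = via - model(conc, *popt)
    diagnostics = {
        "se": {
            "V0": float(se[0]),
            "Imax": float(se[1]),
            "IC50": params.IC50 * float(se[2]),  # delta method from log scale
            **({"gamma": float(se[3])} if fit_gamma else {}),
        },
        "residuals": residuals,
        "rmse": float(np.sqrt(np.mean(residuals**2))),
        "flat_response": params.Imax < 0.05,
    }
    return params, diagnostics


def _profile_ci_1d(
    sse: Callable[[float], float],
    best: float,
    sse_min: float,
    n_obs: int,
    level: float,
    lo_bound: float,
    hi_bound: float,
) -> tuple[float, float]:
    """Profile (F-test) confidence interval for a single least-squares parameter."""
    dof = max(n_obs - 1, 1)
    threshold = sse_min * (1.0 + stats.f.ppf(level, 1, dof) / dof)

    def g(x):
        return sse(x) - threshold

    lo = lo_bound
    if g(lo_bound) > 0:
        lo = optimize.brentq(g, lo_bound, best)
    hi = hi_bound
    if g(hi_bound) > 0:
        hi = optimize.brentq(g, best, hi_bound)
    return float(lo), float(hi)


def fit_interaction_psi(
    checkerboard: pd.DataFrame,
    p_B: HillParams,
    p_D: HillParams,
    ci_level: float = 0.95,
    conc_b_col: str = "drug_b_conc",
    conc_d_col: str = "drug_d_conc",
    viability_col: str = "viability_pct",
) -> tuple[InteractionParams, tuple[float, float]]:
    """One-dimensional least squares for ``psi_vit`` on combination wells,
    with single-agent parameters held fixed; profile-likelihood CI."""
    combo = checkerboard[
        (checkerboard[conc_b_col] > 0) & (checkerboard[conc_d_col] > 0)
    ]
    if combo.empty:
        raise ValueError("checkerboard contains no combination wells")
    cb = combo[conc_b_col].to_numpy(dtype=float)
    cd = combo[conc_d_col].to_numpy(dtype=float)
    via = combo[viability_col].to_numpy(dtype=float)

    def sse(log10_psi: float) -> float:
        pred = ariens_combined_viability(cb, cd, p_B, p_D, 10.0 ** log10_psi)
        return float(np.sum((via - pred) ** 2))

    res = optimize.minimize_scalar(sse, bounds=(-2.0, 2.0), method="bounded")
    best = float(res.x)
    lo, hi = _profile_ci_1d(sse, best, float(res.fun), len(via), ci_level, -2.0, 2.0)
    return InteractionParams(10.0 ** best), (10.0 ** lo, 10.0 ** hi)


# --------------------------------------------------------------------------- #
# pharmacokinetics

@dataclasses.dataclass
class TwoCompartmentParams:
    """Linear two-compartment disposition with optional first-order absorption."""

    CL: float          # clearance, volume/time
    V1: float          # central volume
    Q: float           # intercompartmental clearance
    V2: float          # peripheral volume
    ka: float = 1.0    # absorption rate for extravascular doses, 1/time
    F: float = 1.0     # bioavailability fraction

    def __post_init__(self):
        for name in ("CL", "V1", "Q", "V2", "ka"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.F <= 1:
            raise ValueError("F must lie in (0, 1]")

    @property
    def micro_constants(self) -> tuple[float, float, float]:
        return self.CL / self.V1, self.Q / self.V1, self.Q / self.V2  # k10, k12, k21

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


class ConcentrationProfile:
    """Central-compartment concentration as a superposition of exponential
    terms per dose; exact for linear kinetics."""

    def __init__(self, terms: list[tuple[float, np.ndarray, np.ndarray]]):
        # terms: (dose_time, coefficients, rates) with C += sum(c*exp(r*(t-td)))
        self.terms = terms

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        out = np.zeros_like(t)
        for td, coefs, rates in self.terms:
            dt = t - td
            active = dt >= 0
            if np.any(active):
                out[active] += np.real(
                    np.exp(np.outer(dt[active], rates)) @ coefs
                )
        out = np.maximum(out, 0.0)
        return float(out[0]) if scalar else out


def _dose_terms(p: TwoCompartmentParams, amount: float, route: str):
    k10, k12, k21 = p.micro_constants
    if route == "iv":
        M = np.array([[-(k10 + k12), k21], [k12, -k21]])
        u = np.array([amount, 0.0])
        central = 0
    elif route in ("extravascular", "ip", "oral", "sc"):
        M = np.array(
            [
                [-p.ka, 0.0, 0.0],
                [p.ka, -(k10 + k12), k21],
                [0.0, k12, -k21],
            ]
        )
        u = np.array([p.F * amount, 0.0, 0.0])
        central = 1
    else:
        raise ValueError(f"unknown route {route!r} (use 'iv' or 'extravascular')")
    w, V = np.linalg.eig(M)
    c = V[central, :] * np.linalg.solve(V, u)
    return c / p.V1, w


def two_compartment_profile(
    p: TwoCompartmentParams,
    doses: Sequence[tuple[float, float, str] | Mapping],
) -> ConcentrationProfile:
    """Build the exact concentration-time function for a dosing schedule.

    Doses are (time, amount, route) tuples or {"time_h", "amount", "route"}
    mappings, route 'iv' or 'extravascular' ('ip' accepted as an alias).
    """
    terms = []
    last_t = -np.inf
    for dose in doses:
        if isinstance(dose, Mapping):
            t0, amount, route = dose["time_h"], dose["amount"], dose.get("route", "iv")
        else:
            t0, amount, route = dose
        if t0 < last_t:
            raise ValueError("doses must be sorted by time")
        last_t = t0
        coefs, rates = _dose_terms(p, float(amount), route)
        terms.append((float(t0), coefs, rates))
    return ConcentrationProfile(terms)


def simulate_two_compartment(
    p: TwoCompartmentParams,
    doses: Sequence[tuple[float, float, str] | Mapping],
    times,
) -> np.ndarray:
    """Central concentration at the requested times (closed-form superposition)."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    return two_compartment_profile(p, doses)(times)


def terminal_half_life(p: TwoCompartmentParams) -> float:
    """ln2 / lambda_z with lambda_z the slow disposition eigenvalue."""
    k10, k12, k21 = p.micro_constants
    s = k10 + k12 + k21
    disc = math.sqrt(s * s - 4.0 * k10 * k21)
    lam_z = (s - disc) / 2.0
    return math.log(2.0) / lam_z


def fit_two_compartment(
    times,
    conc,
    doses: Sequence[tuple[float, float, str] | Mapping],
    p0: TwoCompartmentParams | None = None,
) -> TwoCompartmentParams:
    """Least-squares fit of CL, V1, Q, V2 to concentration data (log scale,
    matching a constant-CV error model). Absorption parameters are taken from
    ``p0`` and held fixed (identifiable only with extravascular data)."""
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    keep = conc > 0
    times, conc = times[keep], conc[keep]
    if p0 is None:
        # crude starts: V1 from earliest concentration, CL from naive AUC
        first_amount = (
            doses[0]["amount"] if isinstance(doses[0], Mapping) else doses[0][1]
        )
        v1 = first_amount / max(conc.max(), 1e-12)
        auc = np.trapezoid(conc, times)
        cl = first_amount / max(auc, 1e-12)
        p0 = TwoCompartmentParams(CL=cl, V1=v1, Q=cl, V2=2 * v1)

    def unpack(theta):
        CL, V1, Q, V2 = np.exp(theta)
        return TwoCompartmentParams(CL=CL, V1=V1, Q=Q, V2=V2, ka=p0.ka, F=p0.F)

    def resid(theta):
        pred = simulate_two_compartment(unpack(theta), doses, times)
        return np.log(np.maximum(pred, 1e-30)) - np.log(conc)

    theta0 = np.log([p0.CL, p0.V1, p0.Q, p0.V2])
    sol = optimize.least_squares(resid, theta0, method="lm", max_nfev=20000)
    if not sol.success:
        raise RuntimeError(f"two-compartment fit failed: {sol.message}")
    return unpack(sol.x)


@dataclasses.dataclass
class AllometricCoefficients:
    """Per-parameter power-law coefficients ``X = alpha * BW^beta``."""

    coefficients: dict[str, tuple[float, float]]  # param -> (alpha, beta)

    def predict(self, BW: float) -> dict[str, float]:
        if BW <= 0:
            raise ValueError("body weight must be positive")
        return {k: a * BW**b for k, (a, b) in self.coefficients.items()}


def solve_allometry(
    species_values: Mapping[str, Sequence[tuple[float, float]]],
) -> AllometricCoefficients:
    """Exact two-point solve of ``X = alpha*BW^beta`` for each parameter.

    ``species_values`` maps parameter name to two (BW, X) pairs; the returned
    coefficients reproduce both source species exactly.
    """
    coefs: dict[str, tuple[float, float]] = {}
    for name, pairs in species_values.items():
        if len(pairs) != 2:
            raise ValueError(f"{name!r}: exactly two (BW, X) pairs are required")
        (bw1, x1), (bw2, x2) = pairs
        if min(bw1, bw2, x1, x2) <= 0:
            raise ValueError(f"{name!r}: body weights and values must be positive")
        if bw1 == bw2:
            raise ValueError(f"{name!r}: species body weights must differ")
        beta = math.log(x2 / x1) / math.log(bw2 / bw1)
        alpha = x1 / bw1**beta
        coefs[name] = (alpha, beta)
    return AllometricCoefficients(coefs)


# --------------------------------------------------------------------------- #
# tumor pharmacodynamics

@dataclasses.dataclass
class TumorPDParams:
    """Tumor growth-inhibition parameters with bortezomib resistance onset."""

    TV0: float          # initial tumor volume, mm^3
    kg0: float          # initial first-order growth rate, 1/h
    kgr: float          # exponential decay rate of kg, 1/h
    K_bort: float       # second-order bortezomib kill constant, 1/(conc*h)
    K_dex: float        # second-order dexanabinol kill constant, 1/(conc*h)
    k_res: float        # bortezomib resistance onset rate, 1/h
    psi_viv: float = 1.0  # interaction multiplier on k_res in the combination

    def __post_init__(self):
        if self.TV0 <= 0 or self.kg0 <= 0:
            raise ValueError("TV0 and kg0 must be positive")
        for name in ("kgr", "K_bort", "K_dex", "k_res"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.psi_viv <= 0:
            raise ValueError("psi_viv must be positive")


def tumor_growth_closed_form(TV0: float, kg0: float, kgr: float, t) -> np.ndarray:
    """No-drug tumor volume: ``TV0*exp[(kg0/kgr)(1 - e^(-kgr t))]`` (kgr -> 0
    limit: pure exponential growth)."""
    t = np.asarray(t, dtype=float)
    if kgr < 1e-300:
        v = TV0 * np.exp(kg0 * t)
    else:
        v = TV0 * np.exp(kg0 / kgr * (1.0 - np.exp(-kgr * t)))
    return v if v.shape else float(v)


def simulate_tumor_model(
    p: TumorPDParams,
    times,
    c_bort: Callable | None = None,
    c_dex: Callable | None = None,
    psi: float | None = None,
    dt: float = 0.25,
) -> np.ndarray:
    """Tumor volume at the requested times under concentration forcing.

    The growth term is integrated analytically; the drug-kill terms are
    accumulated by trapezoidal quadrature on a dt-spaced grid refined with the
    output times, then TV = TV0 * exp(growth - kill). ``psi`` overrides
    ``p.psi_viv`` (monotherapy arms use psi = 1: no interaction partner).
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    psi_val = p.psi_viv if psi is None else float(psi)
    if psi_val <= 0:
        raise ValueError("psi must be positive")
    t_max = float(times.max()) if times.size else 0.0
    grid = np.union1d(np.arange(0.0, t_max + dt, dt), times)
    if p.kgr < 1e-300:
        growth = p.kg0 * grid
    else:
        growth = p.kg0 / p.kgr * (1.0 - np.exp(-p.kgr * grid))
    kill_rate = np.zeros_like(grid)
    if c_dex is not None and p.K_dex > 0:
        cd = np.asarray(c_dex(grid), dtype=float)
        if np.any(cd < -1e-9):
            raise ValueError("negative dexanabinol concentrations")
        kill_rate += p.K_dex * np.maximum(cd, 0.0)
    if c_bort is not None and p.K_bort > 0:
        cb = np.asarray(c_bort(grid), dtype=float)
        if np.any(cb < -1e-9):
            raise ValueError("negative bortezomib concentrations")
        kill_rate += p.K_bort * np.exp(-psi_val * p.k_res * grid) * np.maximum(cb, 0.0)
    kill = np.concatenate([[0.0], cumulative_trapezoid(kill_rate, grid)])
    log_tv = math.log(p.TV0) + growth - kill
    idx = np.searchsorted(grid, times)
    return np.exp(log_tv[idx])


@dataclasses.dataclass
class TumorFitResult:
    params: TumorPDParams
    psi_ci: tuple[float, float]
    stage_sse: dict[str, float]
    n_obs: dict[str, int]


class _ArmCache:
    """Pre-evaluated quadrature grid for one study arm.

    Concentration forcing functions are evaluated once on the grid; every
    subsequent objective evaluation is pure vector arithmetic, which keeps the
    staged fit and the profile-likelihood CI cheap.
    """

    def __init__(self, times, tv, c_bort, c_dex, dt):
        self.t_obs = np.asarray(times, dtype=float)
        self.log_tv_obs = np.log(np.asarray(tv, dtype=float))
        t_max = float(self.t_obs.max()) if self.t_obs.size else 0.0
        self.grid = np.union1d(np.arange(0.0, t_max + dt, dt), self.t_obs)
        self.idx = np.searchsorted(self.grid, self.t_obs)
        self.cb = None if c_bort is None else np.maximum(
            np.asarray(c_bort(self.grid), dtype=float), 0.0
        )
        self.cd = None if c_dex is None else np.maximum(
            np.asarray(c_dex(self.grid), dtype=float), 0.0
        )

    def log_tv_pred(self, tv0, kg0, kgr, k_bort, k_dex, k_res, psi):
        grid = self.grid
        if kgr < 1e-300:
            growth = kg0 * grid
        else:
            growth = kg0 / kgr * (1.0 - np.exp(-kgr * grid))
        kill_rate = np.zeros_like(grid)
        if self.cd is not None and k_dex > 0:
            kill_rate = kill_rate + k_dex * self.cd
        if self.cb is not None and k_bort > 0:
            kill_rate = kill_rate + k_bort * np.exp(-psi * k_res * grid) * self.cb
        kill = np.concatenate([[0.0], cumulative_trapezoid(kill_rate, grid)])
        return math.log(tv0) + growth[self.idx] - kill[self.idx]

    def resid(self, tv0, kg0, kgr, k_bort=0.0, k_dex=0.0, k_res=0.0, psi=1.0):
        return self.log_tv_pred(tv0, kg0, kgr, k_bort, k_dex, k_res, psi) - self.log_tv_obs


def _safe_exp(theta):
    return np.exp(np.clip(theta, -60.0, 60.0))


def fit_tumor_study(
    data: pd.DataFrame,
    concentrations: Mapping[str, tuple[Callable | None, Callable | None]],
    roles: Mapping[str, str] | None = None,
    ci_level: float = 0.95,
    dt: float = 0.25,
    ci_method: str = "profile_full",
) -> TumorFitResult:
    """Staged naive-pooled fit of the tumor model across a four-arm study.

    ``data`` columns: arm, animal_id, time_h, tv_mm3. ``concentrations`` maps
    each arm label to its (C_bort, C_dex) forcing functions (None for absent
    drug). ``roles`` maps arm labels to 'control' / 'dex' / 'bort' / 'combo'
    (identity by default). Stages: growth parameters from control; K_dex from
    the dexanabinol arm; K_bort and k_res from the bortezomib arm (psi = 1);
    psi_viv from the combination arm. Residuals are on the log scale, matching
    a proportional error model.

    ``ci_method`` selects the psi_viv interval: ``profile_full`` (default)
    profiles psi while re-optimizing every other parameter against all arms,
    which keeps coverage near nominal; ``profile_conditional`` profiles only
    the combination-arm residuals with earlier stages fixed (cheaper, but
    ignores propagated uncertainty and undercovers).
    """
    if ci_method not in ("profile_full", "profile_conditional"):
        raise ValueError("ci_method must be 'profile_full' or 'profile_conditional'")
    roles = dict(roles) if roles else {}
    arm_of = {role: label for label, role in roles.items()}
    for role in ("control", "dex", "bort", "combo"):
        arm_of.setdefault(role, role)
    if arm_of["control"] not in set(data["arm"]):
        raise ValueError(f"missing control arm {arm_of['control']!r}")

    caches: dict[str, _ArmCache] = {}
    for role in ("control", "dex", "bort", "combo"):
        label = arm_of[role]
        sub = data[data["arm"] == label]
        if sub.empty:
            raise ValueError(f"missing arm {label!r} in tumor data")
        c_b, c_d = (None, None) if role == "control" else concentrations[label]
        caches[role] = _ArmCache(
            sub["time_h"].to_numpy(), sub["tv_mm3"].to_numpy(), c_b, c_d, dt
        )

    stage_sse: dict[str, float] = {}
    n_obs: dict[str, int] = {role: c.t_obs.size for role, c in caches.items()}

    # stage 1: growth from control
    ctl = caches["control"]
    tv0_start = float(np.exp(np.mean(ctl.log_tv_obs[ctl.t_obs == ctl.t_obs.min()])))

    def resid_growth(theta):
        tv0, kg0, kgr = _safe_exp(theta)
        return ctl.resid(tv0, kg0, kgr)

    sol = optimize.least_squares(
        resid_growth, np.log([tv0_start, 0.005, 0.002]), method="lm", max_nfev=20000
    )
    TV0, kg0, kgr = _safe_exp(sol.x)
    stage_sse["control"] = float(np.sum(sol.fun**2))

    # stage 2: K_dex from dexanabinol monotherapy
    dex = caches["dex"]
    res = optimize.minimize_scalar(
        lambda lk: float(np.sum(dex.resid(TV0, kg0, kgr, k_dex=math.exp(lk)) ** 2)),
        bounds=(-25.0, 5.0), method="bounded",
    )
    K_dex = math.exp(float(res.x))
    stage_sse["dex"] = float(res.fun)

    # stage 3: K_bort, k_res from bortezomib monotherapy (psi = 1)
    bort = caches["bort"]

    def resid_bort(theta):
        kb, kr = _safe_exp(theta)
        return bort.resid(TV0, kg0, kgr, k_bort=kb, k_res=kr)

    sol = optimize.least_squares(
        resid_bort, np.log([0.01, 0.01]), method="lm", max_nfev=20000
    )
    K_bort, k_res = _safe_exp(sol.x)
    stage_sse["bort"] = float(np.sum(sol.fun**2))

    # stage 4: psi_viv from the combination
    combo = caches["combo"]

    def sse_psi(psi):
        return float(
            np.sum(combo.resid(TV0, kg0, kgr, K_bort, K_dex, k_res, psi) ** 2)
        )

    lo_b, hi_b = 1e-3, 20.0
    res = optimize.minimize_scalar(
        lambda x: sse_psi(math.exp(x)), bounds=(math.log(lo_b), math.log(hi_b)),
        method="bounded",
    )
    psi_viv = math.exp(float(res.x))
    stage_sse["combo"] = float(res.fun)

    params = TumorPDParams(
        TV0=float(TV0), kg0=float(kg0), kgr=float(kgr),
        K_bort=float(K_bort), K_dex=float(K_dex), k_res=float(k_res),
        psi_viv=float(psi_viv),
    )

    if ci_method == "profile_conditional":
        lo, hi = _profile_ci_1d(
            lambda x: sse_psi(math.exp(x)), math.log(psi_viv), stage_sse["combo"],
            n_obs["combo"], ci_level, math.log(lo_b), math.log(hi_b),
        )
        psi_ci = (math.exp(lo), math.exp(hi))
    else:
        psi_ci = _profile_psi_full(caches, params, ci_level)

    return TumorFitResult(
        params=params, psi_ci=psi_ci, stage_sse=stage_sse, n_obs=n_obs
    )


def _profile_psi_full(
    caches: Mapping[str, _ArmCache], point: TumorPDParams, level: float
) -> tuple[float, float]:
    """Profile-likelihood CI for psi_viv with all other parameters
    re-optimized against all arms at each candidate psi."""
    theta0 = np.log(
        [point.TV0, point.kg0, point.kgr, point.K_bort, point.k_res, point.K_dex]
    )

    def joint_resid(theta, psi):
        tv0, kg0, kgr, kb, kr, kd = _safe_exp(theta)
        return np.concatenate(
            [
                caches["control"].resid(tv0, kg0, kgr),
                caches["dex"].resid(tv0, kg0, kgr, k_dex=kd),
                caches["bort"].resid(tv0, kg0, kgr, k_bort=kb, k_res=kr),
                caches["combo"].resid(tv0, kg0, kgr, kb, kd, kr, psi),
            ]
        )

    def sse(psi: float) -> float:
        sol = optimize.least_squares(
            joint_resid, theta0, args=(psi,), method="lm", max_nfev=10_000
        )
        return float(np.sum(sol.fun**2))

    n = sum(c.t_obs.size for c in caches.values())
    n_par = 7
    best = point.psi_viv
    smin = sse(best)
    dof = max(n - n_par, 1)
    threshold = smin * (1.0 + stats.f.ppf(level, 1, dof) / dof)

    def g(log_psi: float) -> float:
        return sse(math.exp(log_psi)) - threshold

    lo_b, hi_b = math.log(1e-2), math.log(20.0)
    log_best = math.log(best)
    lo = math.exp(optimize.brentq(g, lo_b, log_best, xtol=1e-3)) if g(lo_b) > 0 else math.exp(lo_b)
    hi = math.exp(optimize.brentq(g, log_best, hi_b, xtol=1e-3)) if g(hi_b) > 0 else math.exp(hi_b)
    return (lo, hi)
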