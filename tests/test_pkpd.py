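"""Viability models, two-compartment PK, allometric scaling, tumor PD."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from neuroqsp.pkpd import (
    HillParams,
    InteractionParams,
    TumorPDParams,
    TwoCompartmentParams,
    ariens_combined_viability,
    bliss_classification,
    fit_interaction_psi,
    fit_single_agent,
    fit_tumor_study,
    fit_two_compartment,
    hill_viability,
    simulate_tumor_model,
    simulate_two_compartment,
    solve_allometry,
    terminal_half_life,
    tumor_growth_closed_form,
    two_compartment_profile,
)
from neuroqsp.synthetic import (
    DEX_HUMAN_PK,
    DEX_RAT_PK,
    generate_tumor_study,
    generate_viability_plate,
)


class TestHillViability:
    def test_baseline_at_zero(self):
        p = HillParams(V0=100, Imax=0.9, IC50=5)
        assert hill_viability(0.0, p) == pytest.approx(100.0)

    def test_half_maximal_at_ic50(self):
        p = HillParams(V0=100, Imax=1.0, IC50=5)
        assert hill_viability(5.0, p) == pytest.approx(50.0)

    def test_high_concentration_limit(self):
        p = HillParams(V0=100, Imax=0.8, IC50=5)
        assert hill_viability(1e9, p) == pytest.approx(20.0, rel=1e-4)

    def test_monotone_non_increasing(self):
        p = HillParams(V0=100, Imax=1.0, IC50=2, gamma=2)
        conc = np.logspace(-3, 3, 40)
        assert np.all(np.diff(hill_viability(conc, p)) <= 0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            hill_viability(-1.0, HillParams(100, 1, 1))


class TestAriens:
    pB = HillParams(V0=100, Imax=1.0, IC50=2.0)
    pD = HillParams(V0=100, Imax=1.0, IC50=20.0)

    def test_reduces_to_single_agent(self):
        assert ariens_combined_viability(3.0, 0.0, self.pB, self.pD, 1.0) == pytest.approx(
            hill_viability(3.0, self.pB)
        )
        assert ariens_combined_viability(0.0, 7.0, self.pB, self.pD, 1.0) == pytest.approx(
            hill_viability(7.0, self.pD)
        )

    def test_both_at_ic50_gives_third(self):
        # r_B = r_D = 1 -> V0 * (1 - 2/3)
        assert ariens_combined_viability(2.0, 20.0, self.pB, self.pD, 1.0) == pytest.approx(100 / 3)

    def test_antagonism_raises_viability(self):
        low = ariens_combined_viability(2.0, 10.0, self.pB, self.pD, 1.0)
        high = ariens_combined_viability(2.0, 10.0, self.pB, self.pD, 2.0)
        assert high > low

    def test_bounded_and_non_increasing(self):
        grid = np.linspace(0, 50, 30)
        v = [ariens_combined_viability(c, 5.0, self.pB, self.pD, 1.5) for c in grid]
        assert np.all(np.diff(v) <= 1e-12)
        assert min(v) >= 0 and max(v) <= 100

    def test_invalid_psi_rejected(self):
        with pytest.raises(ValueError):
            ariens_combined_viability(1, 1, self.pB, self.pD, 0.0)


class TestBliss:
    def test_expected_formula(self):
        out = bliss_classification(0.5, 0.5, 0.75)
        assert out["expected"] == pytest.approx(0.75)
        assert out["label"] == "additive"

    def test_single_agent_consistency(self):
        assert bliss_classification(0.0, 0.3, 0.3)["label"] == "additive"

    def test_synergy_and_antagonism_labels(self):
        assert bliss_classification(0.3, 0.3, 0.75)["label"] == "synergy"
        assert bliss_classification(0.3, 0.3, 0.30)["label"] == "antagonism"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bliss_classification(1.2, 0.1, 0.1)


class TestSingleAgentFit:
    def test_noise_free_exact_recovery(self):
        truth = HillParams(V0=100, Imax=0.9, IC50=5, gamma=1)
        conc = np.array([0.0, 0.1, 0.5, 1, 5, 10, 50, 100])
        plate = pd.DataFrame({"conc": conc, "viability_pct": hill_viability(conc, truth)})
        params, diag = fit_single_agent(plate)
        assert params.IC50 == pytest.approx(5.0, rel=1e-4)
        assert params.Imax == pytest.approx(0.9, rel=1e-4)
        assert not diag["flat_response"]

    def test_noisy_recovery_within_ten_percent(self):
        rng = np.random.default_rng(12)
        truth = HillParams(V0=100, Imax=0.9, IC50=5, gamma=1)
        conc = np.repeat([0.05, 0.2, 1, 5, 20, 100, 500], 3)
        via = hill_viability(conc, truth) * rng.lognormal(
            -0.5 * np.log(1.0025), np.sqrt(np.log(1.0025)), conc.size
        )
        params, _ = fit_single_agent(pd.DataFrame({"conc": conc, "viability_pct": via}))
        assert abs(params.IC50 - 5.0) / 5.0 < 0.10

    def test_monotone_increasing_input_flagged(self):
        conc = np.array([0.1, 1, 10, 100, 1000])
        plate = pd.DataFrame({"conc": conc, "viability_pct": 100 + 5 * np.log10(conc)})
        try:
            params, diag = fit_single_agent(plate)
        except RuntimeError:
            return  # convergence failure is an accepted outcome
        assert diag["flat_response"]

    def test_too_few_concentrations_rejected(self):
        plate = pd.DataFrame({"conc": [0, 1, 2], "viability_pct": [100, 60, 30]})
        with pytest.raises(ValueError, match="4 distinct"):
            fit_single_agent(plate)


class TestInteractionFit:
    def test_psi_two_recovered_within_ten_percent(self):
        plate, truth = generate_viability_plate(psi=2.0, cv=0.05, seed=5)
        params, ci = fit_interaction_psi(plate, truth["p_B"], truth["p_D"])
        assert abs(params.psi_vit - 2.0) / 2.0 < 0.10
        assert ci[0] < params.psi_vit < ci[1]

    def test_additive_data_ci_contains_one(self):
        plate, truth = generate_viability_plate(psi=1.0, cv=0.05, seed=8)
        params, ci = fit_interaction_psi(plate, truth["p_B"], truth["p_D"])
        assert ci[0] <= 1.0 <= ci[1]

    def test_single_agent_only_wells_rejected(self):
        plate, truth = generate_viability_plate(psi=1.0, cv=0.0, seed=0)
        single = plate[(plate.drug_b_conc == 0) | (plate.drug_d_conc == 0)]
        with pytest.raises(ValueError, match="combination"):
            fit_interaction_psi(single, truth["p_B"], truth["p_D"])


class TestTwoCompartment:
    params = TwoCompartmentParams(CL=2.0, V1=10.0, Q=3.0, V2=20.0)

    def test_iv_bolus_initial_concentration(self):
        c = simulate_two_compartment(self.params, [(0.0, 50.0, "iv")], [0.0])
        assert c[0] == pytest.approx(50.0 / 10.0, rel=1e-6)

    def test_superposition_of_two_doses(self):
        t = np.linspace(0, 48, 97)
        one = simulate_two_compartment(self.params, [(0.0, 50.0, "iv")], t)
        shifted = simulate_two_compartment(self.params, [(12.0, 50.0, "iv")], t)
        both = simulate_two_compartment(
            self.params, [(0.0, 50.0, "iv"), (12.0, 50.0, "iv")], t
        )
        assert np.allclose(both, one + shifted, rtol=1e-9)

    def test_terminal_slope_equals_lambda_z(self):
        t = np.linspace(100, 200, 51)
        c = simulate_two_compartment(self.params, [(0.0, 50.0, "iv")], t)
        slope = np.polyfit(t, np.log(c), 1)[0]
        lam_z = math.log(2) / terminal_half_life(self.params)
        assert slope == pytest.approx(-lam_z, rel=1e-6)

    def test_matches_ode_integration_oracle(self):
        # independent check of the closed-form superposition
        k10, k12, k21 = self.params.micro_constants

        def rhs(t, y):
            return [-(k10 + k12) * y[0] + k21 * y[1], k12 * y[0] - k21 * y[1]]

        sol = solve_ivp(rhs, (0, 24), [50.0, 0.0], rtol=1e-10, atol=1e-12,
                        t_eval=np.linspace(0, 24, 25))
        closed = simulate_two_compartment(self.params, [(0.0, 50.0, "iv")], sol.t)
        assert np.allclose(closed, sol.y[0] / 10.0, rtol=1e-7)

    def test_extravascular_starts_at_zero(self):
        p = TwoCompartmentParams(CL=2, V1=10, Q=3, V2=20, ka=1.0, F=0.8)
        c = simulate_two_compartment(p, [(0.0, 50.0, "extravascular")], [0.0, 1.0])
        assert c[0] == pytest.approx(0.0, abs=1e-9)
        assert c[1] > 0

    def test_unknown_route_rejected(self):
        with pytest.raises(ValueError, match="route"):
            simulate_two_compartment(self.params, [(0.0, 1.0, "topical")], [1.0])

    def test_refit_recovers_parameters(self):
        t = np.array([0.083, 0.25, 0.5, 1, 2, 4, 8, 12, 24])
        conc = simulate_two_compartment(DEX_RAT_PK, [(0.0, 2.5, "iv")], t)
        fit = fit_two_compartment(t, conc, [(0.0, 2.5, "iv")])
        for name in ("CL", "V1", "Q", "V2"):
            assert getattr(fit, name) == pytest.approx(getattr(DEX_RAT_PK, name), rel=1e-3)


class TestAllometry:
    def test_two_point_solution(self):
        ac = solve_allometry({"X": [(0.25, 1.0), (70.0, 56.0)]})
        alpha, beta = ac.coefficients["X"]
        assert beta == pytest.approx(0.7144, abs=1e-3)
        assert alpha == pytest.approx(2.69, abs=0.01)
        assert ac.predict(0.02)["X"] == pytest.approx(0.165, abs=0.002)

    def test_round_trips_both_source_species(self):
        ac = solve_allometry({"CL": [(0.25, 0.06), (70.0, 25.0)]})
        assert ac.predict(0.25)["CL"] == pytest.approx(0.06, rel=1e-12)
        assert ac.predict(70.0)["CL"] == pytest.approx(25.0, rel=1e-12)

    def test_target_equal_to_source(self):
        ac = solve_allometry({"X": [(1.0, 3.0), (10.0, 9.0)]})
        assert ac.predict(10.0)["X"] == pytest.approx(9.0)

    def test_constant_parameter_gives_zero_exponent(self):
        ac = solve_allometry({"X": [(0.25, 5.0), (70.0, 5.0)]})
        alpha, beta = ac.coefficients["X"]
        assert beta == 0.0 and alpha == pytest.approx(5.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            solve_allometry({"X": [(0.25, -1.0), (70.0, 56.0)]})


class TestTumorModel:
    def test_no_drug_closed_form_value(self):
        assert tumor_growth_closed_form(100, 0.01, 0.001, 100.0) == pytest.approx(
            259.0, abs=0.1
        )

    def test_no_drug_simulation_matches_closed_form(self):
        p = TumorPDParams(100, 0.01, 0.001, 0, 0, 0)
        t = np.linspace(0, 10_000, 21)  # 10x the kgr time constant
        sim = simulate_tumor_model(p, t)
        assert np.allclose(sim, tumor_growth_closed_form(100, 0.01, 0.001, t), rtol=1e-6)

    def test_zero_kgr_limit_is_exponential(self):
        p = TumorPDParams(100, 0.01, 0.0, 0, 0, 0)
        sim = simulate_tumor_model(p, [0.0, 50.0])
        assert sim[1] == pytest.approx(100 * math.exp(0.5), rel=1e-9)

    def test_matches_ode_oracle_with_drug(self):
        p = TumorPDParams(100, 0.006, 0.002, 0.05, 0.0, 0.0076, psi_viv=0.9)
        c_b = lambda t: 0.5 * np.exp(-0.01 * np.asarray(t))

        def rhs(t, y):
            kg = 0.006 * math.exp(-0.002 * t)
            kill = 0.05 * math.exp(-0.9 * 0.0076 * t) * 0.5 * math.exp(-0.01 * t)
            return [(kg - kill) * y[0]]

        t = np.linspace(0, 672, 15)
        sol = solve_ivp(rhs, (0, 672), [100.0], rtol=1e-10, atol=1e-10, t_eval=t)
        sim = simulate_tumor_model(p, t, c_bort=c_b, dt=0.05)
        assert np.allclose(sim, sol.y[0], rtol=1e-5)

    def test_smaller_psi_means_smaller_tumor(self):
        p = TumorPDParams(100, 0.006, 0.002, 0.05, 0.0, 0.0076)
        c_b = lambda t: np.full_like(np.asarray(t, dtype=float), 0.3)
        t = [200.0, 672.0]
        low = simulate_tumor_model(p, t, c_bort=c_b, psi=0.7)
        high = simulate_tumor_model(p, t, c_bort=c_b, psi=1.3)
        assert np.all(low < high)

    def test_negative_concentration_rejected(self):
        p = TumorPDParams(100, 0.006, 0.002, 0.05, 0.0, 0.0076)
        with pytest.raises(ValueError, match="negative"):
            simulate_tumor_model(p, [10.0], c_bort=lambda t: -np.ones_like(t))


class TestTumorStudyFit:
    def test_noise_free_self_consistency(self):
        study, truth = generate_tumor_study(cv=0.0, seed=2)
        fit = fit_tumor_study(study, truth["concentrations"])
        p, t = fit.params, truth["params"]
        assert p.TV0 == pytest.approx(t.TV0, rel=1e-3)
        assert p.kg0 == pytest.approx(t.kg0, rel=1e-3)
        assert p.kgr == pytest.approx(t.kgr, rel=1e-3)
        assert p.K_bort == pytest.approx(t.K_bort, rel=1e-3)
        assert p.K_dex == pytest.approx(t.K_dex, rel=1e-2)
        assert p.k_res == pytest.approx(t.k_res, rel=1e-3)
        assert p.psi_viv == pytest.approx(t.psi_viv, rel=1e-2)

    def test_refitting_single_agent_stages_is_order_consistent(self):
        # noise-free staged estimates do not move when refit on their own arm
        study, truth = generate_tumor_study(cv=0.0, seed=3)
        first = fit_tumor_study(study, truth["concentrations"])
        second = fit_tumor_study(study, truth["concentrations"])
        assert first.params == second.params

    def test_additive_truth_ci_contains_one(self):
        from neuroqsp.synthetic import DEFAULT_TUMOR_PARAMS
        import dataclasses

        params = dataclasses.replace(DEFAULT_TUMOR_PARAMS, psi_viv=1.0)
        study, truth = generate_tumor_study(params=params, cv=0.10, seed=21)
        fit = fit_tumor_study(study, truth["concentrations"])
        assert fit.psi_ci[0] <= 1.0 <= fit.psi_ci[1]

    def test_missing_control_arm_rejected(self):
        study, truth = generate_tumor_study(cv=0.0, seed=0)
        with pytest.raises(ValueError, match="control"):
            fit_tumor_study(study[study.arm != "control"], truth["concentrations"])
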