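"""Circuit assembly and steady-state integration: source closed forms,
Kirchhoff bookkeeping, periodicity, mass conservation, solver cross-check."""

import numpy as np
import pytest
from scipy.integrate import quad

from lumpedheart.elastance import elastance_value
from lumpedheart.errors import DomainError
from lumpedheart.network import (SolverSettings, assemble_rhs, cycle_volumes,
                                 initial_state, netlist_text, pulmonary_source,
                                 simulate_to_steady)
from lumpedheart.records import CirculationParams
from lumpedheart.valves import build_patient_valves
from tests.helpers import make_record


class TestPulmonarySource:
    def test_sine_peak_and_silence(self):
        q, t_ee, T = 350.0, 0.3, 0.9
        assert pulmonary_source(t_ee / 2, q, t_ee, T) == pytest.approx(q)
        assert pulmonary_source(t_ee + 1e-6, q, t_ee, T) == 0.0
        assert pulmonary_source(T - 1e-6, q, t_ee, T) == 0.0

    def test_cycle_volume_matches_closed_form(self):
        q, t_ee, T = 412.7, 0.31, 0.85
        vol, err = quad(lambda t: pulmonary_source(t, q, t_ee, T), 0.0, T,
                        points=[t_ee], limit=200)
        assert vol == pytest.approx(2 * q * t_ee / np.pi, rel=1e-10)

    def test_wraps_modulo_period(self):
        q, t_ee, T = 300.0, 0.3, 0.8
        assert pulmonary_source(0.1 + 5 * T, q, t_ee, T) == pytest.approx(
            pulmonary_source(0.1, q, t_ee, T))

    def test_invalid_duration_rejected(self):
        with pytest.raises(DomainError):
            pulmonary_source(0.1, 300.0, 1.2, 0.8)


class TestAssembleRhs:
    def test_source_free_equilibrium(self):
        # no pulmonary inflow, every node at the venous pressure, chambers
        # loaded so their elastance pressure equals it too: nothing moves
        rec = make_record()
        params = CirculationParams(Q_MPV=0.0)
        valves = build_patient_valves(rec)
        t = 0.123
        T = rec.T
        p_cv = params.P_CV0
        e_lv = elastance_value(t, params.elastance_LV, T)
        t_la = (t - params.la_phase_frac * T) % T
        e_la = elastance_value(t_la, params.elastance_LA, T)
        y = np.zeros(12)
        y[0] = params.V0_LV + p_cv / e_lv
        y[1] = params.V0_LA + p_cv / e_la
        y[2:6] = p_cv
        dy = assemble_rhs(y, t, params, valves, rec)
        assert np.abs(dy).max() < 1e-9

    def test_kirchhoff_volume_bookkeeping(self, rng):
        # at arbitrary states, the summed storage rates (chambers + C·dP of
        # every capacitor) must equal source inflow minus venous outflow
        rec = make_record(EOA_AR=0.2, EOA_MR=0.3)
        params = CirculationParams(R_ub=5.0)
        valves = build_patient_valves(rec)
        for _ in range(25):
            y = np.empty(12)
            y[0] = params.V0_LV + rng.uniform(20, 200)
            y[1] = params.V0_LA + rng.uniform(20, 200)
            y[2:6] = rng.uniform(2, 150, size=4)
            y[6:12] = rng.uniform(0, 400, size=6)
            t = rng.uniform(0, rec.T)
            dy = assemble_rhs(y, t, params, valves, rec)
            storage = (dy[0] + dy[1] + params.C_ao * dy[2] + params.C_SAC * dy[3]
                       + params.C_PA * dy[4] + params.C_PVC * dy[5])
            # independent Ohm's-law bookkeeping for the venous outflows
            q_ub = (y[3] - params.P_CV0) / params.R_ub
            q_desc = (y[3] - params.P_CV0) / (
                params.R_pda + params.R_SA + params.R_SV)
            q_src = pulmonary_source(t, params.Q_MPV, rec.T_EJ, rec.T)
            assert storage == pytest.approx(q_src - q_ub - q_desc, abs=1e-8)


class TestSteadyState:
    def test_periodicity_and_volume_drift(self, nominal_steady):
        params, valves, waves, info = nominal_steady
        assert info.converged
        sv = cycle_volumes(waves)["aortic_forward"]
        # per-chamber drift over the recorded cycle < 0.5% of stroke volume
        assert abs(waves.V_LV[-1] - waves.V_LV[0]) < 0.005 * sv
        assert abs(waves.V_LA[-1] - waves.V_LA[0]) < 0.005 * sv

    def test_mass_conservation_between_stations(self, nominal_steady):
        _, _, waves, _ = nominal_steady
        vols = cycle_volumes(waves)
        pulm = vols["pulmonary"]
        assert vols["aortic_forward"] - vols["aortic_regurgitant"] == (
            pytest.approx(pulm, rel=0.01))
        assert vols["mitral_forward"] - vols["mitral_regurgitant"] == (
            pytest.approx(pulm, rel=0.01))

    def test_mass_conservation_with_regurgitation(self, tuned_r_ub):
        rec = make_record(EOA_AR=0.25, EOA_MR=0.2)
        params = CirculationParams(R_ub=tuned_r_ub, Q_MPV=370.0)
        waves, info = simulate_to_steady(params, build_patient_valves(rec), rec)
        assert info.converged
        vols = cycle_volumes(waves)
        assert vols["aortic_regurgitant"] > 0.1  # the reverse branch conducts
        pulm = vols["pulmonary"]
        assert vols["aortic_forward"] - vols["aortic_regurgitant"] == (
            pytest.approx(pulm, rel=0.01))
        assert vols["mitral_forward"] - vols["mitral_regurgitant"] == (
            pytest.approx(pulm, rel=0.01))

    def test_pressures_within_sanity_bounds(self, nominal_steady):
        params, _, waves, _ = nominal_steady
        for arr in (waves.P_LV, waves.P_LA, waves.P_ao, waves.P_sa):
            assert arr.max() < 400.0
        assert waves.P_ao.min() > params.P_CV0

    def test_upper_body_split_after_tuning(self, nominal_steady):
        _, _, waves, _ = nominal_steady
        vols = cycle_volumes(waves)
        frac = vols["upper_body"] / (vols["upper_body"] + vols["descending"])
        assert 0.145 <= frac <= 0.155

    def test_looser_tolerance_never_needs_more_cycles(self, nominal_record):
        params = CirculationParams(Q_MPV=360.0)
        valves = build_patient_valves(nominal_record)
        n = {}
        for tol in (1e-6, 2e-6):
            _, info = simulate_to_steady(params, valves, nominal_record,
                                         SolverSettings(steady_tol=tol))
            n[tol] = info.n_cycles
        assert n[2e-6] <= n[1e-6]

    def test_deterministic_repeatability(self, nominal_record):
        params = CirculationParams(Q_MPV=360.0)
        valves = build_patient_valves(nominal_record)
        w1, _ = simulate_to_steady(params, valves, nominal_record)
        w2, _ = simulate_to_steady(params, valves, nominal_record)
        assert np.array_equal(w1.P_LV, w2.P_LV)
        assert np.array_equal(w1.Q_AV, w2.Q_AV)

    def test_implicit_integrator_cross_check(self, nominal_steady):
        # the recorded fixed-step RK4 cycle against an independent implicit
        # variable-step (Radau) integration of the same cycle from the same
        # periodic start state: only the integration scheme differs
        params, valves, waves, info = nominal_steady
        from lumpedheart.network import integrate_single_cycle
        from tests.helpers import make_record
        rec = make_record(forward_lvot_sv=70.0, EOA_AV=3.0,
                          VTI_LVOT=70.0 / 3.14159265, VTI_AO=70.0 / 3.0)
        w_im = integrate_single_cycle(params, valves, rec, info.y_start)
        assert w_im.P_ao.max() == pytest.approx(waves.P_ao.max(), rel=5e-3)
        assert w_im.P_ao.min() == pytest.approx(waves.P_ao.min(), rel=5e-3)
        assert np.max(np.abs(w_im.V_LV - waves.V_LV)) < 2.5  # mL (sharp-edge shift)
        sv_rk4 = cycle_volumes(waves)["aortic_forward"]
        sv_im = cycle_volumes(w_im)["aortic_forward"]
        assert sv_im == pytest.approx(sv_rk4, rel=5e-3)

    def test_step_refinement_convergence(self, nominal_record, tuned_r_ub):
        # halving the fixed step leaves the periodic solution unchanged to
        # well below the cross-check tolerances
        params = CirculationParams(R_ub=tuned_r_ub, Q_MPV=360.0)
        valves = build_patient_valves(nominal_record)
        w1, _ = simulate_to_steady(params, valves, nominal_record)
        w2, _ = simulate_to_steady(params, valves, nominal_record,
                                   SolverSettings(initial_dt=5e-5))
        assert w2.P_ao.max() == pytest.approx(w1.P_ao.max(), rel=1e-5)
        assert w2.P_ao.min() == pytest.approx(w1.P_ao.min(), rel=1e-5)

    def test_netlist_dump_mentions_every_element(self, nominal_record):
        params = CirculationParams()
        text = netlist_text(params, build_patient_valves(nominal_record),
                            nominal_record)
        for token in ("C_PA", "C_PVC", "C_SAC", "C_ao", "R_ub", "R_pda",
                      "R_SA", "R_SV", "P_CV0", "valve AV", "valve MV"):
            assert token in text

    def test_initial_state_is_cold(self, nominal_record):
        y0 = initial_state(CirculationParams(), nominal_record)
        assert np.all(y0[2:] == 0.0)  # capacitors and inductors start at zero
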