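"""Closed-loop left-heart + systemic + pulmonary circuit as an ODE system.

Netlist (every circuit element appears exactly once, in its anatomical
position; ``--`` marks series elements, ``[C]`` a capacitor to ground,
``>|`` a gated valve branch):

    pulmonary source Q_PV(t)  -->  node PA [C_PA]
    node PA  -- R_PA -- R_PC -- L_PC -->  node PVC [C_PVC]
    node PVC -- R_PVC -- R_PV -- L_PV -->  left atrium (elastance chamber)
    LA  >| MV (forward)  / |< MR (reverse)  >|  left ventricle (elastance)
    LV  >| AV (forward)  / |< AR (reverse)  >|  node AO [C_ao]
    node AO -- R_ao --> arterial junction [C_SAC]
    junction -- R_ub --> venous node (fixed P_CV0)
    junction -- R_pda -- R_SA -- R_SV --> venous node (fixed P_CV0)

The arterial junction — where the upper-body branch and the descending
aorta split off — carries the systemic compliance C_SAC.  Both
compliances thus sit upstream of the peripheral resistance (windkessel
arrangement): the arterial pool holds diastolic pressure with the
physiological decay time ≈ (C_ao + C_SAC)·(R_pda + R_SA + R_SV), and the
two compliances act nearly in parallel for the pulse pressure, which is
what lets the cuff pressures identify their sum (the split itself is not
observable from two pressures; see the estimation module).
The pulmonary source is a rectified sine of amplitude Q_MPV and duration
t_ee (the ejection time), zero for the rest of the cycle, standing in for
the right heart.  The venous node is clamped at the constant central
venous pressure P_CV0.

Integration uses a fixed-step classical Runge-Kutta scheme on the
(non-stiff at the chosen step) gated system, with the gated valve flows
projected onto Q ≥ 0 after every step; :func:`integrate_single_cycle`
offers an independent implicit variable-step (Radau) integration of one
cycle for cross-checking the discretisation.  The circuit is cycled from zeroed
capacitor pressures and inductor flows until the start-of-cycle state is
periodic to ``steady_tol`` in relative L∞ norm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _integrator as _core
from .elastance import elastance_value
from .errors import DomainError, SolverError, ValidationError
from .records import CirculationParams, PatientRecord, WaveformSet
from .valves import ValveBranch

__all__ = ["SolverSettings", "SteadyInfo", "pulmonary_source", "pack_params",
           "assemble_rhs", "initial_state", "simulate_to_steady",
           "integrate_single_cycle", "netlist_text", "cycle_volumes"]

_VALVE_ORDER = ("AV", "AR", "MV", "MR")


@dataclass
class SolverSettings:
    """Numerical controls for the cycle integration.

    ``initial_dt`` is the fixed Runge-Kutta step (the grid spacing of the
    returned waveforms); ``rtol``/``atol`` apply only to the Radau
    single-cycle cross-check.  ``steady_tol`` is the relative L∞ change of the
    cycle-start state between consecutive cycles below which the solution
    is declared periodic.
    """

    initial_dt: float = 1e-4  # s
    rtol: float = 1e-8
    atol: float = 1e-8
    max_cycles: int = 150
    steady_tol: float = 1e-6
    accelerate: bool = True  # dominant-mode extrapolation of the cycle map

    def __post_init__(self) -> None:
        if self.initial_dt <= 0 or self.max_cycles < 1 or self.steady_tol <= 0:
            raise ValidationError("invalid solver settings")


@dataclass
class SteadyInfo:
    """Diagnostics of one steady-state solve."""

    n_cycles: int
    converged: bool
    rel_change: float
    y_start: np.ndarray  # converged cycle-start state (reusable as warm start)
    volumes_above_unloaded: bool = True


def pulmonary_source(t, Q_MPV: float, t_ee: float, T: float):
    """Rectified-sine pulmonary valve flow (mL/s): Q_MPV·sin(πt/t_ee) for
    t ≤ t_ee within the cycle, zero for t_ee < t ≤ T."""
    if not (0 < t_ee <= T):
        raise DomainError(f"need 0 < t_ee ≤ T, got t_ee={t_ee}, T={T}")
    tm = np.mod(np.asarray(t, dtype=float), T)
    out = np.where(tm <= t_ee, Q_MPV * np.sin(np.pi * tm / t_ee), 0.0)
    return float(out) if out.ndim == 0 else out


def pack_params(params: CirculationParams, valves: Sequence[ValveBranch],
                rec: PatientRecord) -> np.ndarray:
    """Pack parameters, elastances and valve coefficients into the flat
    vector consumed by the compiled right-hand side."""
    T = rec.T
    p = np.zeros(_core.NPARAM)
    p[_core.IP_R_AO] = params.R_ao
    p[_core.IP_R_SV] = params.R_SV
    p[_core.IP_R_PDA] = params.R_pda
    p[_core.IP_R_SA] = params.R_SA
    p[_core.IP_R_UB] = params.R_ub
    p[_core.IP_C_AO] = params.C_ao
    p[_core.IP_C_SAC] = params.C_SAC
    p[_core.IP_C_PA] = params.C_PA
    p[_core.IP_C_PVC] = params.C_PVC
    p[_core.IP_L_PV] = params.L_PV
    p[_core.IP_L_PC] = params.L_PC
    p[_core.IP_R_PV] = params.R_PV
    p[_core.IP_R_PVC] = params.R_PVC
    p[_core.IP_R_PC] = params.R_PC
    p[_core.IP_R_PA] = params.R_PA
    p[_core.IP_P_CV0] = params.P_CV0
    p[_core.IP_Q_MPV] = params.Q_MPV
    p[_core.IP_T_EE] = rec.T_EJ
    p[_core.IP_T] = T
    for base, ep in ((_core.IP_LV_E, params.elastance_LV),
                     (_core.IP_LA_E, params.elastance_LA)):
        p[base] = ep.E_max
        p[base + 1] = ep.E_min
        p[base + 2] = ep.m1
        p[base + 3] = ep.m2
        p[base + 4] = ep.tau1_frac * T
        p[base + 5] = ep.tau2_frac * T
    p[_core.IP_V0_LV] = params.V0_LV
    p[_core.IP_V0_LA] = params.V0_LA
    p[_core.IP_LA_SHIFT] = params.la_phase_frac * T
    by_kind = {v.kind: v for v in valves}
    for k, kind in enumerate(_VALVE_ORDER):
        base = _core.IP_VALVE + 3 * k
        v = by_kind.get(kind)
        if v is not None:
            p[base] = 1.0
            p[base + 1] = v.inertance_coeff
            p[base + 2] = v.bernoulli_coeff
    return p


def assemble_rhs(state: np.ndarray, t: float, params: CirculationParams,
                 valves: Sequence[ValveBranch], rec: PatientRecord) -> np.ndarray:
    """Evaluate d(state)/dt for the packed 12-component state vector.

    Chamber volume derivatives are inflow − outflow, capacitor pressure
    derivatives net current over C, and inductor flow derivatives follow
    from the branch pressure balances (valve branches through their
    inverted net-pressure-gradient relations).
    """
    p = pack_params(params, valves, rec)
    y = np.asarray(state, dtype=float)
    if y.shape != (_core.NSTATE,):
        raise ValidationError(f"state must have shape ({_core.NSTATE},)")
    dy = np.empty(_core.NSTATE)
    _core.rhs(float(t), y, p, dy)
    if not np.all(np.isfinite(dy)):
        raise SolverError(f"non-finite derivative at t={t}: state={y!r}, dy={dy!r}")
    return dy


def initial_state(params: CirculationParams, rec: PatientRecord) -> np.ndarray:
    """Cold-start state: zeroed capacitor pressures and inductor/valve flows,
    chambers loaded at nominal volumes (the periodic orbit is independent of
    this choice)."""
    y0 = np.zeros(_core.NSTATE)
    y0[0] = max(rec.EDV, params.V0_LV + 50.0)
    y0[1] = params.V0_LA + 40.0
    return y0


def _derived_waves(hist: np.ndarray, p: np.ndarray, params: CirculationParams,
                   rec: PatientRecord, dt: float) -> WaveformSet:
    n = hist.shape[0]
    T = rec.T
    t = np.arange(n) * dt
    t[-1] = T  # guard against accumulated round-off on the last node
    P_LV = elastance_value(t, params.elastance_LV, T) * (hist[:, 0] - params.V0_LV)
    t_la = np.mod(t - params.la_phase_frac * T, T)
    P_LA = elastance_value(t_la, params.elastance_LA, T) * (hist[:, 1] - params.V0_LA)
    P_ao = hist[:, 2]
    P_sac = hist[:, 3]
    return WaveformSet(
        t=t,
        P_LV=P_LV,
        P_LA=P_LA,
        P_ao=P_ao,
        P_sa=P_sac,
        V_LV=hist[:, 0],
        V_LA=hist[:, 1],
        Q_AV=hist[:, 6],
        Q_AR=hist[:, 7],
        Q_MV=hist[:, 8],
        Q_MR=hist[:, 9],
        Q_PV=pulmonary_source(t, params.Q_MPV, rec.T_EJ, T),
        Q_ub=(P_sac - params.P_CV0) / params.R_ub,
        Q_sa=(P_sac - params.P_CV0) / (params.R_pda + params.R_SA + params.R_SV),
    )


def simulate_to_steady(params: CirculationParams, valves: Sequence[ValveBranch],
                       rec: PatientRecord, settings: Optional[SolverSettings] = None,
                       y0: Optional[np.ndarray] = None):
    """Integrate the circuit to periodic steady state.

    Returns ``(WaveformSet, SteadyInfo)``.  Non-convergence within
    ``max_cycles`` is flagged on the :class:`SteadyInfo`, not raised; only
    non-finite state aborts with :class:`~lumpedheart.errors.SolverError`.
    """
    settings = settings or SolverSettings()
    p = pack_params(params, valves, rec)
    nsteps = max(100, int(round(rec.T / settings.initial_dt)))
    dt = rec.T / nsteps
    if y0 is None:
        y0 = initial_state(params, rec)
    y0 = np.asarray(y0, dtype=float).copy()

    hist, n_cycles, rel, converged = _core.run_to_steady(
        y0, p, dt, nsteps, settings.max_cycles, settings.steady_tol,
        settings.accelerate)

    if not np.all(np.isfinite(hist)):
        raise SolverError(
            f"non-finite state after {n_cycles} cycles; last cycle-start "
            f"state: {hist[0]!r}"
        )
    waves = _derived_waves(hist, p, params, rec, dt)
    info = SteadyInfo(
        n_cycles=int(n_cycles),
        converged=bool(converged),
        rel_change=float(rel),
        y_start=hist[0].copy(),
        volumes_above_unloaded=bool(
            hist[:, 0].min() > params.V0_LV and hist[:, 1].min() > params.V0_LA
        ),
    )
    return waves, info


def integrate_single_cycle(params: CirculationParams,
                           valves: Sequence[ValveBranch], rec: PatientRecord,
                           y0: np.ndarray, rtol: float = 1e-6,
                           atol: float = 1e-6) -> WaveformSet:
    """Integrate exactly one cycle with an implicit variable-step scheme
    (Radau IIA) on the standard output grid.

    Used as an independent cross-check of the fixed-step discretisation:
    started from the same (e.g. converged periodic) state, only the
    integration scheme differs from :func:`simulate_to_steady`.  The
    ideal-diode valve gating is discontinuous, which defeats implicit
    step-size/Newton control, so this path integrates the smooth-diode
    variant of the field (reverse regime = large finite leak resistance,
    blended over ~0.05 mL/s); the back-leak it admits is < 0.01 mL per
    cycle.  Repeated cycling with a variable-step method is deliberately
    not offered; the fixed-step projected scheme is the production path.
    """
    from scipy.integrate import solve_ivp

    p = pack_params(params, valves, rec)
    nsteps = max(100, int(round(rec.T / SolverSettings().initial_dt)))
    dt = rec.T / nsteps
    grid = np.arange(nsteps + 1) * dt
    grid[-1] = rec.T

    def fun(t, y):
        dy = np.empty(_core.NSTATE)
        _core.rhs_smooth(t, y, p, dy, 0.05)
        return dy

    sol = solve_ivp(fun, (0.0, rec.T), np.asarray(y0, dtype=float),
                    method="Radau", t_eval=grid, rtol=rtol, atol=atol)
    if not sol.success:
        raise SolverError(f"single-cycle Radau integration failed: {sol.message}")
    hist = sol.y.T.copy()
    hist[:, 6:10] = np.maximum(hist[:, 6:10], 0.0)
    return _derived_waves(hist, p, params, rec, dt)


def cycle_volumes(waves: WaveformSet) -> dict:
    """Cycle integrals (mL) of every flow in the waveform set, for mass
    bookkeeping: at steady state the pulmonary source volume equals the net
    transmitral and net aortic forward volumes."""
    t = waves.t
    return {
        "pulmonary": float(np.trapezoid(waves.Q_PV, t)),
        "aortic_forward": float(np.trapezoid(waves.Q_AV, t)),
        "aortic_regurgitant": float(np.trapezoid(waves.Q_AR, t)),
        "mitral_forward": float(np.trapezoid(waves.Q_MV, t)),
        "mitral_regurgitant": float(np.trapezoid(waves.Q_MR, t)),
        "upper_body": float(np.trapezoid(waves.Q_ub, t)),
        "descending": float(np.trapezoid(waves.Q_sa, t)),
    }


def netlist_text(params: CirculationParams, valves: Sequence[ValveBranch],
                 rec: PatientRecord) -> str:
    """Human-readable netlist of the assembled circuit, for audit."""
    lines = [
        "closed-loop left-heart circuit netlist",
        f"  source   : Q_PV(t) = {params.Q_MPV:.4g}·sin(pi t/{rec.T_EJ:.4g}) mL/s, "
        f"0 for t in ({rec.T_EJ:.4g}, {rec.T:.4g}] s",
        f"  node PA  : C_PA = {params.C_PA} mL/mmHg",
        f"  PA->PVC  : R_PA = {params.R_PA} + R_PC = {params.R_PC} mmHg·s/mL, "
        f"L_PC = {params.L_PC} mmHg·s²/mL",
        f"  node PVC : C_PVC = {params.C_PVC} mL/mmHg",
        f"  PVC->LA  : R_PVC = {params.R_PVC} + R_PV = {params.R_PV} mmHg·s/mL, "
        f"L_PV = {params.L_PV} mmHg·s²/mL",
        f"  LA       : double-Hill elastance {params.elastance_LA}, "
        f"V0 = {params.V0_LA} mL, phase shift {params.la_phase_frac}·T",
        f"  LV       : double-Hill elastance {params.elastance_LV}, "
        f"V0 = {params.V0_LV} mL",
        f"  node AO  : C_ao = {params.C_ao} mL/mmHg",
        f"  AO->junction: R_ao = {params.R_ao} mmHg·s/mL",
        f"  junction : C_SAC = {params.C_SAC:.4g} mL/mmHg",
        f"  junction->venous: R_ub = {params.R_ub:.4g} mmHg·s/mL (upper body)",
        f"  junction->venous: R_pda = {params.R_pda} + R_SA = {params.R_SA:.4g} "
        f"+ R_SV = {params.R_SV} mmHg·s/mL (descending)",
        f"  venous   : fixed P_CV0 = {params.P_CV0} mmHg",
    ]
    for v in valves:
        lines.append(
            f"  valve {v.kind}: EOA = {v.eoa} cm², "
            f"L = {v.inertance_coeff:.6g} mmHg·s²/mL, "
            f"B = {v.bernoulli_coeff:.6g} mmHg·s²/mL²"
        )
    return "\n".join(lines) + "\n"
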