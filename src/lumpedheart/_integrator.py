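"""Numba-compiled right-hand side and fixed-step cycle integrator.

The circuit state is packed into a 12-vector and all constants into a flat
parameter vector so the whole per-cycle integration loop can be JIT
compiled.  Layouts are defined here once and shared with
:mod:`lumpedheart.network`, which owns the user-facing API and documents
the netlist.

State vector layout::

    0  V_LV    mL      LV volume
    1  V_LA    mL      LA volume
    2  P_Cao   mmHg    aortic capacitor (C_ao) pressure
    3  P_CSAC  mmHg    systemic arterial capacitor (C_SAC) pressure
    4  P_CPA   mmHg    pulmonary arterial capacitor (C_PA) pressure
    5  P_CPVC  mmHg    pulmonary venous capacitor (C_PVC) pressure
    6  Q_AV    mL/s    aortic forward valve flow      (gated ≥ 0)
    7  Q_AR    mL/s    aortic regurgitant flow        (gated ≥ 0, aorta→LV)
    8  Q_MV    mL/s    mitral forward valve flow      (gated ≥ 0)
    9  Q_MR    mL/s    mitral regurgitant flow        (gated ≥ 0, LV→LA)
    10 Q_LPC   mL/s    pulmonary capillary inductor flow
    11 Q_LPV   mL/s    pulmonary vein inductor flow
"""

from __future__ import annotations

import numpy as np
from numba import njit

NSTATE = 12

# --- parameter vector indices ---------------------------------------------
IP_R_AO = 0
IP_R_SV = 1
IP_R_PDA = 2
IP_R_SA = 3
IP_R_UB = 4
IP_C_AO = 5
IP_C_SAC = 6
IP_C_PA = 7
IP_C_PVC = 8
IP_L_PV = 9
IP_L_PC = 10
IP_R_PV = 11
IP_R_PVC = 12
IP_R_PC = 13
IP_R_PA = 14
IP_P_CV0 = 15
IP_Q_MPV = 16
IP_T_EE = 17
IP_T = 18
# LV elastance: E_max, E_min, m1, m2, tau1 (s), tau2 (s), V0
IP_LV_E = 19  # ..24
IP_V0_LV = 25
# LA elastance + shift
IP_LA_E = 26  # ..31
IP_V0_LA = 32
IP_LA_SHIFT = 33
# valves: (present, L, B) × (AV, AR, MV, MR)
IP_VALVE = 34
NPARAM = IP_VALVE + 12

# switching relaxation time for a closed branch caught below zero flow, s
_T_RELAX = 1e-3
# reverse-leak resistance (mmHg·s/mL) of the smooth diode used by the
# implicit cross-check path: large enough that back-leak volume per cycle
# is < 0.01 mL, small enough to keep the field smooth
_R_LEAK = 1e4


@njit(cache=False)
def _elastance(t, Emax, Emin, m1, m2, tau1, tau2):
    if t <= 0.0:
        return Emin
    a = (t / tau1) ** m1
    b = (t / tau2) ** m2
    return 0.5 * (Emax - Emin) * (a / (1.0 + a)) / (1.0 + b) + Emin


@njit(cache=False)
def rhs(t, y, p, dy):
    """Time derivative of the packed state (hard-gated diodes); writes
    into ``dy``."""
    _rhs_impl(t, y, p, dy, 0.0)


@njit(cache=False)
def rhs_smooth(t, y, p, dy, eps):
    """Variant with smooth diode switching for implicit integrators: the
    reverse regime is a large finite leak resistance blended over a flow
    width ``eps`` (mL/s), so the field is continuous and Newton iterations
    cannot lock onto a spurious closed branch."""
    _rhs_impl(t, y, p, dy, eps)


@njit(cache=False)
def _rhs_impl(t, y, p, dy, smooth_eps):
    T = p[IP_T]
    tm = t % T
    # chamber pressures
    e_lv = _elastance(tm, p[IP_LV_E], p[IP_LV_E + 1], p[IP_LV_E + 2],
                      p[IP_LV_E + 3], p[IP_LV_E + 4], p[IP_LV_E + 5])
    P_LV = e_lv * (y[0] - p[IP_V0_LV])
    t_la = (tm - p[IP_LA_SHIFT]) % T
    e_la = _elastance(t_la, p[IP_LA_E], p[IP_LA_E + 1], p[IP_LA_E + 2],
                      p[IP_LA_E + 3], p[IP_LA_E + 4], p[IP_LA_E + 5])
    P_LA = e_la * (y[1] - p[IP_V0_LA])

    P_ao = y[2]
    P_sac = y[3]
    P_pa = y[4]
    P_pvc = y[5]
    P_cv = p[IP_P_CV0]

    # systemic arterial pool: the junction downstream of R_ao carries the
    # systemic compliance C_SAC and feeds two drain paths to the venous
    # node — the upper body (R_ub) and the descending path
    # R_pda + R_SA + R_SV (windkessel: compliance upstream of the
    # peripheral resistance).
    Q_rao = (P_ao - P_sac) / p[IP_R_AO]
    Q_ub_ = (P_sac - P_cv) / p[IP_R_UB]
    Q_sa = (P_sac - P_cv) / (p[IP_R_PDA] + p[IP_R_SA] + p[IP_R_SV])

    # pulmonary source (rectified sine, one arch per cycle)
    if tm <= p[IP_T_EE]:
        Q_src = p[IP_Q_MPV] * np.sin(np.pi * tm / p[IP_T_EE])
    else:
        Q_src = 0.0

    # valve branches: driving pressure per orientation
    q_av = y[6]
    q_ar = y[7]
    q_mv = y[8]
    q_mr = y[9]
    for k in range(4):
        base = IP_VALVE + 3 * k
        if p[base] <= 0.0:
            dy[6 + k] = 0.0
            continue
        q = y[6 + k]
        if k == 0:
            dp = P_LV - P_ao
        elif k == 1:
            dp = P_ao - P_LV
        elif k == 2:
            dp = P_LA - P_LV
        else:
            dp = P_LV - P_LA
        if smooth_eps > 0.0:
            # leak blend centred at q = -2eps so forward opening is unimpeded
            s_rev = 0.5 * (1.0 - np.tanh((q + 2.0 * smooth_eps) / smooth_eps))
            dy[6 + k] = (dp - p[base + 2] * q * abs(q)
                         - _R_LEAK * s_rev * q) / p[base + 1]
        elif q > 0.0 or dp > 0.0:
            dy[6 + k] = (dp - p[base + 2] * q * abs(q)) / p[base + 1]
        else:
            dy[6 + k] = -q / _T_RELAX  # pull a closed branch back to zero flow

    # chambers
    dy[0] = q_mv + q_ar - q_av - q_mr
    dy[1] = y[11] + q_mr - q_mv
    # capacitors
    dy[2] = (q_av - q_ar - Q_rao) / p[IP_C_AO]
    dy[3] = (Q_rao - Q_ub_ - Q_sa) / p[IP_C_SAC]
    dy[4] = (Q_src - y[10]) / p[IP_C_PA]
    dy[5] = (y[10] - y[11]) / p[IP_C_PVC]
    # pulmonary inductor lines
    dy[10] = (P_pa - P_pvc - (p[IP_R_PA] + p[IP_R_PC]) * y[10]) / p[IP_L_PC]
    dy[11] = (P_pvc - P_LA - (p[IP_R_PVC] + p[IP_R_PV]) * y[11]) / p[IP_L_PV]


@njit(cache=False)
def _rk4_cycle(y, p, dt, nsteps, record, hist):
    """Advance one full cardiac cycle in place; optionally record states."""
    k1 = np.empty(NSTATE)
    k2 = np.empty(NSTATE)
    k3 = np.empty(NSTATE)
    k4 = np.empty(NSTATE)
    yt = np.empty(NSTATE)
    if record:
        hist[0, :] = y
    t = 0.0
    for i in range(nsteps):
        rhs(t, y, p, k1)
        for j in range(NSTATE):
            yt[j] = y[j] + 0.5 * dt * k1[j]
        rhs(t + 0.5 * dt, yt, p, k2)
        for j in range(NSTATE):
            yt[j] = y[j] + 0.5 * dt * k2[j]
        rhs(t + 0.5 * dt, yt, p, k3)
        for j in range(NSTATE):
            yt[j] = y[j] + dt * k3[j]
        rhs(t + dt, yt, p, k4)
        for j in range(NSTATE):
            y[j] += dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        # complementarity clamp: gated branch flows stay non-negative
        for k in range(4):
            if y[6 + k] < 0.0:
                y[6 + k] = 0.0
        t += dt
        if record:
            hist[i + 1, :] = y


@njit(cache=False)
def run_to_steady(y0, p, dt, nsteps, max_cycles, steady_tol, accelerate):
    """Cycle the circuit until the start-of-cycle state is periodic.

    The cycle-start state obeys a contractive fixed-point map whose slowest
    mode (set by the large pulmonary venous compliance) decays only ~7% per
    cycle.  When ``accelerate`` is set, the dominant mode is removed every
    few cycles by Aitken-style geometric extrapolation: with successive
    differences d0, d1 of the cycle-start state, the dominant eigenvalue is
    estimated as λ = <d1,d0>/<d0,d0> (in scale-normalised inner products)
    and the state advanced by d1·λ/(1−λ).  Convergence is always judged on
    a raw, un-extrapolated pair of consecutive cycles.

    Returns ``(hist, n_cycles, rel_change, converged)`` where ``hist`` is the
    fully recorded final cycle (nsteps+1 × NSTATE) integrated from the
    converged cycle-start state.
    """
    y = y0.copy()
    yprev = np.empty(NSTATE)
    yprev2 = np.empty(NSTATE)
    hist = np.empty((nsteps + 1, NSTATE))
    rel = 1e30
    n_cycles = 0
    converged = False
    since_extrap = 0
    for _cyc in range(max_cycles):
        yprev2[:] = yprev
        yprev[:] = y
        _rk4_cycle(y, p, dt, nsteps, False, hist)
        n_cycles += 1
        since_extrap += 1
        rel = 0.0
        for j in range(NSTATE):
            scale = max(abs(y[j]), abs(yprev[j]), 1.0)
            d = abs(y[j] - yprev[j]) / scale
            if d > rel:
                rel = d
        if not np.isfinite(rel):
            return hist, n_cycles, rel, False
        if rel < steady_tol and since_extrap >= 2:
            converged = True
            break
        if accelerate and since_extrap >= 3:
            num = 0.0
            den = 0.0
            for j in range(NSTATE):
                s = max(abs(y[j]), 1.0)
                d1 = (y[j] - yprev[j]) / s
                d0 = (yprev[j] - yprev2[j]) / s
                num += d1 * d0
                den += d0 * d0
            if den > 0.0:
                lam = num / den
                if 0.2 < lam < 0.995:
                    f = lam / (1.0 - lam)
                    for j in range(NSTATE):
                        y[j] += (y[j] - yprev[j]) * f
                    for k in range(4):
                        if y[6 + k] < 0.0:
                            y[6 + k] = 0.0
                    since_extrap = 0
    _rk4_cycle(y, p, dt, nsteps, True, hist)
    return hist, n_cycles, rel, converged
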