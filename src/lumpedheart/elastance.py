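"""Double-Hill time-varying elastance and pressure-volume coupling.

Each heart chamber (LV, LA) is a single compartment whose pressure is tied
to its volume through a time-varying elastance

    E(t) = N · [ (t/τ1)^m1 / (1 + (t/τ1)^m1) ] · [ 1 / (1 + (t/τ2)^m2) ] + E_min

with N = (E_max − E_min)/2.  The first bracket describes contraction, the
second relaxation; τ1/τ2 translate and m1/m2 shape the two limbs.  Both
brackets lie in [0, 1], so E is bounded by E_min and (E_max + E_min)/2 and
E(0) = E_min exactly.  Chamber pressure follows P(t) = E(t)·(V(t) − V0)
with V0 the unloaded volume.

Time is taken modulo the cardiac period T, so multi-cycle integrations can
evaluate the elastance without wrapping on the caller side.  The atrial
elastance is evaluated on a shifted axis (see
:attr:`lumpedheart.records.CirculationParams.la_phase_frac`) so that atrial
contraction lands late in diastole, just before ventricular activation.
"""

from __future__ import annotations

import numpy as np

from .errors import CalibrationError, DomainError
from .records import ElastanceParams

__all__ = ["elastance_value", "chamber_pressure", "adjust_unloaded_volume"]


def elastance_value(t, p: ElastanceParams, T: float):
    """Evaluate the double-Hill elastance (mmHg/mL) at time ``t`` (s).

    ``t`` may be a scalar or array; it is taken modulo the period ``T``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("elastance time must be non-negative")
    if T <= 0:
        raise DomainError(f"period T must be positive, got {T}")
    tm = np.mod(t, T)
    tau1 = p.tau1_frac * T
    tau2 = p.tau2_frac * T
    a = (tm / tau1) ** p.m1
    b = (tm / tau2) ** p.m2
    out = p.N * (a / (1.0 + a)) / (1.0 + b) + p.E_min
    return float(out) if out.ndim == 0 else out


def chamber_pressure(V: float, V0: float, t: float, p: ElastanceParams, T: float):
    """Chamber pressure P = E(t)·(V − V0) in mmHg.

    Raises for V ≤ V0: the elastance coupling assumes the chamber is loaded
    above its unloaded volume throughout the simulation.
    """
    if np.any(np.asarray(V) <= V0):
        raise DomainError(f"chamber volume {V} must exceed unloaded volume V0={V0}")
    return elastance_value(t, p, T) * (np.asarray(V, dtype=float) - V0)


def adjust_unloaded_volume(simulated_EDV: float, measured_EDV: float, V0: float) -> float:
    """Shift the unloaded volume so the simulated end-diastolic volume matches
    the measured one.

    Because pressure depends on volume only through (V − V0), adding a
    constant to V0 translates the whole P-V loop along the volume axis
    without changing pressures or flows; a single re-simulation therefore
    reproduces the measured EDV, and ESV follows from the (unchanged)
    simulated stroke volume.
    """
    if simulated_EDV <= 0 or measured_EDV <= 0:
        raise DomainError("EDV values must be positive")
    v0_new = V0 + (measured_EDV - simulated_EDV)
    if measured_EDV <= v0_new:
        raise CalibrationError(
            f"adjusted V0={v0_new:.2f} mL would not stay below the measured "
            f"EDV={measured_EDV:.2f} mL"
        )
    return v0_new
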