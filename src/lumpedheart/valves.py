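"""Nonlinear valve branch elements.

Each valve is a series combination of a flow-dependent (Bernoulli)
resistance and a constant inertance, expressed through the net
transvalvular pressure gradient:

    aortic side (AV forward, AR reverse):
        ΔP = [2πρ / √(E_LCo)] · dQ/dt + [ρ / (2·E_LCo²)] · Q²
        E_LCo = EOA·A / (A − EOA)      (A = ascending-aorta area for the AV,
                                        LVOT area for the AR branch)
    mitral side (MV forward, MR reverse):
        ΔP = [M_MV / EOA] · dQ/dt + [ρ / (2·EOA²)] · Q²

with ρ the blood density and M_MV = 0.53 g/cm² the mitral inertance
constant.  The bracketed coefficients are evaluated in CGS (g, cm, s →
dyn/cm²) and converted to mmHg once, through the declared constant
1 mmHg = 1333.22 dyn/cm².

Every branch is diode-gated: it conducts only in its forward orientation
(flow ≥ 0 along the branch arrow); the switching rule itself lives in the
network integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .errors import DomainError, StateError, ValidationError
from .records import PatientRecord
from .units import BLOOD_DENSITY_G_PER_ML, DYN_CM2_PER_MMHG

__all__ = ["ValveBranch", "energy_loss_coefficient", "net_pressure_gradient",
           "build_patient_valves"]


def energy_loss_coefficient(eoa: float, A: float) -> float:
    """Valvular energy-loss coefficient E_LCo = EOA·A/(A − EOA), cm².

    Accounts for downstream pressure recovery; diverges as the orifice
    approaches the duct area, hence the strict ``eoa < A`` requirement.
    """
    if eoa <= 0:
        raise DomainError(f"EOA must be positive, got {eoa}")
    if eoa >= A:
        raise DomainError(
            f"EOA={eoa} cm² must be smaller than the reference area A={A} cm²"
        )
    return eoa * A / (A - eoa)


@dataclass
class ValveBranch:
    """One gated valve branch with precomputed mmHg-unit coefficients.

    ``inertance_coeff`` multiplies dQ/dt (mmHg·s²/mL) and
    ``bernoulli_coeff`` multiplies Q² (mmHg·s²/mL²).
    """

    kind: str  # one of "AV", "AR", "MV", "MR"
    eoa: float  # cm²
    reference_area: Optional[float] = None  # cm²; A_AO for AV, A_LVOT for AR
    el_co: Optional[float] = None  # cm², aortic-side branches only
    inertance_coeff: float = 0.0
    bernoulli_coeff: float = 0.0
    rho: float = BLOOD_DENSITY_G_PER_ML
    M_MV: float = 0.53

    def __post_init__(self) -> None:
        if self.kind not in ("AV", "AR", "MV", "MR"):
            raise ValidationError(f"unknown valve kind '{self.kind}'")
        if self.eoa <= 0:
            raise DomainError(f"EOA must be positive, got {self.eoa}")
        if self.kind in ("AV", "AR"):
            if self.reference_area is None:
                raise ValidationError(f"{self.kind} branch needs a reference area")
            self.el_co = energy_loss_coefficient(self.eoa, self.reference_area)
            area = self.el_co
            self.inertance_coeff = (
                2.0 * math.pi * self.rho / math.sqrt(area) / DYN_CM2_PER_MMHG
            )
        else:
            area = self.eoa
            self.inertance_coeff = self.M_MV / area / DYN_CM2_PER_MMHG
        self.bernoulli_coeff = self.rho / (2.0 * area**2) / DYN_CM2_PER_MMHG


def net_pressure_gradient(branch: ValveBranch, Q: float, dQdt: float) -> float:
    """Instantaneous net pressure gradient (mmHg) across a valve branch for
    flow ``Q`` (mL/s) and flow acceleration ``dQdt`` (mL/s²)."""
    if branch.inertance_coeff <= 0 or branch.bernoulli_coeff <= 0:
        raise StateError(f"valve branch {branch.kind} has uninitialised coefficients")
    return branch.inertance_coeff * dQdt + branch.bernoulli_coeff * Q * abs(Q)


def build_patient_valves(rec: PatientRecord) -> list[ValveBranch]:
    """Build the patient's valve branches from Doppler measurements.

    The forward AV and MV branches are always present.  Reverse
    (regurgitant) branches are included only when the corresponding
    regurgitant orifice area was measured — for patients with no
    insufficiency the reverse branch is simply absent from the circuit.
    """
    rho = BLOOD_DENSITY_G_PER_ML
    valves = [
        ValveBranch(kind="AV", eoa=rec.EOA_AV, reference_area=rec.A_AO, rho=rho),
        ValveBranch(kind="MV", eoa=rec.mitral_area, rho=rho),
    ]
    if rec.EOA_AR is not None:
        if rec.EOA_AR >= rec.A_LVOT:
            raise ValidationError(
                f"EOA_AR={rec.EOA_AR} cm² must be smaller than A_LVOT={rec.A_LVOT:.4f} cm²"
            )
        valves.append(
            ValveBranch(kind="AR", eoa=rec.EOA_AR, reference_area=rec.A_LVOT, rho=rho)
        )
    if rec.EOA_MR is not None:
        valves.append(ValveBranch(kind="MR", eoa=rec.EOA_MR, rho=rho))
    return valves
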