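"""Pointwise St. Venant-Kirchhoff solid-mechanics kernels, Robin pressure
boundary-condition coefficients, and a reduced surrogate for diastolic
Young's-modulus calibration.

The passive LV wall is modelled as an isotropic St. Venant-Kirchhoff
hyperelastic solid: the second Piola-Kirchhoff stress is linear in the
Green-Lagrange strain,

    Σ = λ·tr(E)·I + 2µ·E,      E = ½(∇u + ∇uᵀ + ∇u·∇uᵀ) = ½(FᵀF − I),

with F = I + (∇u)ᵀ the deformation gradient (note the transpose in this
convention — many texts write F = I + ∇u) and (λ, µ) the Lamé constants of
the Young's modulus/Poisson ratio pair.  The Cauchy stress follows by the
push-forward σ = (1/det F)·F·Σ·Fᵀ.

For a partitioned fluid-structure coupling, wall inertia enters the fluid
pressure equation through a Robin condition p + (ρ_s·h_s/ρ)·∂p/∂n = 0
whose effective thickness h_s = Δt·√((λ+2µ)/ρ_s) is the distance a
dilatational wave travels per time step.

Young's-modulus calibration reproduces the procedure of matching a
diastolic pressure-volume limb by interpolating E — but on a declared
thin-walled spherical-shell surrogate chamber (membrane equilibrium by the
Laplace relation, SVK plane-stress law linking pressure to the volume
ratio) instead of a meshed ventricle, so the procedure is testable at desk
scale.  The surrogate is a pluggable stand-in, not a 3-D solid solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import CalibrationError, DomainError, ValidationError
from .units import PA_PER_MMHG

__all__ = ["Tensor3", "MaterialParams", "lame_constants", "lame_to_young",
           "green_lagrange_strain", "svk_second_piola", "cauchy_from_second_piola",
           "robin_coefficients", "SphericalShellChamber", "calibrate_young_modulus"]

Tensor3 = np.ndarray  # 3×3 real second-order tensor, row-major semantics

_I3 = np.eye(3)
_SYM_TOL = 1e-12


def _as_tensor(A) -> Tensor3:
    A = np.asarray(A, dtype=float)
    if A.shape != (3, 3):
        raise ValidationError(f"expected a 3×3 tensor, got shape {A.shape}")
    if not np.all(np.isfinite(A)):
        raise ValidationError("tensor has non-finite entries")
    return A


def lame_constants(young_E: float, poisson_nu: float) -> tuple[float, float]:
    """Lamé constants (λ, µ) in Pa from Young's modulus (Pa) and Poisson
    ratio: λ = Eν/((1+ν)(1−2ν)), µ = E/(2(1+ν))."""
    if young_E <= 0:
        raise DomainError(f"Young's modulus must be positive, got {young_E}")
    if not (-1.0 < poisson_nu < 0.5):
        raise DomainError(
            f"Poisson ratio must lie in (−1, 0.5) (ν=0.5 is the incompressible "
            f"limit), got {poisson_nu}"
        )
    lam = young_E * poisson_nu / ((1.0 + poisson_nu) * (1.0 - 2.0 * poisson_nu))
    mu = young_E / (2.0 * (1.0 + poisson_nu))
    return lam, mu


def lame_to_young(lam: float, mu: float) -> tuple[float, float]:
    """Inverse map (λ, µ) → (E, ν)."""
    if mu <= 0:
        raise DomainError("shear modulus must be positive")
    young = mu * (3.0 * lam + 2.0 * mu) / (lam + mu)
    nu = lam / (2.0 * (lam + mu))
    return young, nu


@dataclass
class MaterialParams:
    """Isotropic solid material: Young's modulus (Pa), Poisson ratio, the
    consistent Lamé pair, and density (kg/m³)."""

    young_E: float
    poisson_nu: float
    rho_s: float = 1050.0  # kg/m³ (configurable; myocardium ≈ blood density)
    lame_lambda: float = 0.0
    lame_mu: float = 0.0

    def __post_init__(self) -> None:
        if self.rho_s <= 0:
            raise DomainError("solid density must be positive")
        self.lame_lambda, self.lame_mu = lame_constants(self.young_E, self.poisson_nu)


def green_lagrange_strain(F: Tensor3) -> Tensor3:
    """Green-Lagrange strain E = ½(FᵀF − I), equivalently
    ½(∇u + ∇uᵀ + ∇u·∇uᵀ) with ∇u = Fᵀ − I under the F = I + (∇u)ᵀ
    convention.  Symmetric by construction and exactly zero for rigid
    rotations."""
    F = _as_tensor(F)
    if np.linalg.det(F) <= 0:
        raise DomainError(f"deformation gradient has det F = {np.linalg.det(F):.3g} ≤ 0")
    return 0.5 * (F.T @ F - _I3)


def svk_second_piola(Estrain: Tensor3, lam: float, mu: float) -> Tensor3:
    """Second Piola-Kirchhoff stress Σ = λ·tr(E)·I + 2µ·E (isotropic
    Hooke's law in the Green-Lagrange strain)."""
    E = _as_tensor(Estrain)
    scale = max(1.0, float(np.abs(E).max()))
    if np.abs(E - E.T).max() > _SYM_TOL * scale:
        raise DomainError("strain tensor must be symmetric")
    return lam * np.trace(E) * _I3 + 2.0 * mu * E


def cauchy_from_second_piola(F: Tensor3, Sigma: Tensor3) -> Tensor3:
    """Cauchy stress by push-forward: σ = (1/det F)·F·Σ·Fᵀ."""
    F = _as_tensor(F)
    Sigma = _as_tensor(Sigma)
    J = np.linalg.det(F)
    if J <= 0:
        raise DomainError(f"deformation gradient has det F = {J:.3g} ≤ 0")
    return (F @ Sigma @ F.T) / J


def robin_coefficients(dt: float, mat: MaterialParams, rho_fluid: float) -> dict:
    """Coefficients of the interface Robin pressure condition
    p + α·∂p/∂n = 0 that lets the fluid solver feel wall inertia:
    h_s = Δt·√((λ+2µ)/ρ_s) (m) and α = ρ_s·h_s/ρ_fluid (m)."""
    if dt <= 0 or rho_fluid <= 0:
        raise DomainError("time step and fluid density must be positive")
    h_s = dt * math.sqrt((mat.lame_lambda + 2.0 * mat.lame_mu) / mat.rho_s)
    return {"h_s": h_s, "alpha": mat.rho_s * h_s / rho_fluid}


# ---------------------------------------------------------------------------
# surrogate-chamber Young's modulus calibration
# ---------------------------------------------------------------------------


@dataclass
class SphericalShellChamber:
    """Thin-walled spherical SVK membrane as a surrogate passive chamber.

    Quasi-static inflation: for cavity volume V the equibiaxial membrane
    stretch is λ_s = (V/V_unloaded)^{1/3}; plane stress through the wall
    fixes the radial strain, the SVK law gives the membrane second
    Piola-Kirchhoff stress, and the Laplace relation
    P = 2·σ_θ·h/R converts the pushed-forward hoop stress to cavity
    pressure.  P(V; E) is linear in E and strictly increasing in V, which
    makes the calibration a clean one-dimensional root-find.
    """

    unloaded_volume_ml: float
    wall_thickness_cm: float
    poisson_nu: float = 0.3

    def __post_init__(self) -> None:
        if self.unloaded_volume_ml <= 0 or self.wall_thickness_cm <= 0:
            raise DomainError("chamber geometry must be positive")

    def pressure_mmhg(self, V_ml, young_E_pa: float):
        """Quasi-static cavity pressure (mmHg) at cavity volume(s) V (mL)."""
        if young_E_pa <= 0:
            raise DomainError("Young's modulus must be positive")
        V = np.asarray(V_ml, dtype=float)
        if np.any(V < self.unloaded_volume_ml * (1 - 1e-12)):
            raise DomainError("volumes below the unloaded volume are not admissible")
        lam, mu = lame_constants(young_E_pa, self.poisson_nu)
        lam_s = (V / self.unloaded_volume_ml) ** (1.0 / 3.0)  # membrane stretch
        E_t = 0.5 * (lam_s**2 - 1.0)  # tangential Green strain
        E_r = -2.0 * lam * E_t / (lam + 2.0 * mu)  # plane stress Σ_rr = 0
        if np.any(1.0 + 2.0 * E_r <= 0):
            raise DomainError("radial contraction beyond admissible stretch")
        lam_r = np.sqrt(1.0 + 2.0 * E_r)  # radial (thickness) stretch
        sigma_t = lam_s**2 * (lam * (2.0 * E_t + E_r) + 2.0 * mu * E_t) / (
            lam_s**2 * lam_r)  # pushed-forward hoop Cauchy stress, Pa
        R0_cm = (3.0 * self.unloaded_volume_ml / (4.0 * math.pi)) ** (1.0 / 3.0)
        geom = 2.0 * (self.wall_thickness_cm * lam_r) / (R0_cm * lam_s)  # 2h/R
        P_pa = sigma_t * geom
        out = P_pa / PA_PER_MMHG
        return float(out) if out.ndim == 0 else out


def calibrate_young_modulus(target_P_mmhg: np.ndarray, target_V_ml: np.ndarray,
                            chamber: SphericalShellChamber,
                            bracket_pa: tuple[float, float] = (1e3, 1e7)) -> dict:
    """Interpolate the Young's modulus that best matches a diastolic
    pressure-volume limb on the surrogate chamber.

    The signed mean pressure mismatch g(E) = mean(P_model(V; E) − P_target)
    is strictly increasing in E (the shell pressure is linear in E), so a
    bracketing root-find on g both locates the least-squares optimum of the
    mismatch and certifies it.  Returns the calibrated modulus together
    with the residual L2 mismatch.
    """
    P = np.asarray(target_P_mmhg, dtype=float)
    V = np.asarray(target_V_ml, dtype=float)
    if P.shape != V.shape or P.ndim != 1 or len(P) < 2:
        raise ValidationError("target limb needs matching 1-D P and V arrays, n ≥ 2")
    if np.any(np.diff(V) <= 0):
        raise ValidationError("target diastolic limb must be monotone in V")

    def mismatch(E):
        return float(np.mean(chamber.pressure_mmhg(V, E) - P))

    lo, hi = bracket_pa
    g_lo, g_hi = mismatch(lo), mismatch(hi)
    if g_lo * g_hi > 0:
        raise CalibrationError(
            f"bracket [{lo:.3g}, {hi:.3g}] Pa does not change the sign of the "
            f"mismatch (endpoint mismatches {g_lo:+.3g}, {g_hi:+.3g} mmHg)"
        )
    E_star = float(brentq(mismatch, lo, hi, rtol=1e-10))
    resid = chamber.pressure_mmhg(V, E_star) - P
    return {
        "young_E": E_star,
        "l2_mismatch_mmhg": float(np.sqrt(np.mean(resid**2))),
        "max_mismatch_mmhg": float(np.abs(resid).max()),
    }
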