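"""Domain types, unit conventions and readers/writers for patient records,
circulation parameter sets and simulated waveform output.

A :class:`PatientRecord` holds the quantities derivable from a routine
Doppler-echocardiography exam (stroke volume through the left ventricular
outflow tract, valve effective orifice areas, chamber volumes, timing) plus
cuff systolic/diastolic brachial pressures.  These are the only inputs the
simulator needs: no catheterisation, no imaging-derived geometry.

Records are serialised as flat JSON with a ``schema_version`` stamp;
waveforms are written as CSV with one column per field.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError, ValidationError

SCHEMA_VERSION = "1"

__all__ = [
    "PatientRecord",
    "ElastanceParams",
    "CirculationParams",
    "WaveformSet",
    "FittedPatient",
    "load_patient",
    "save_patient",
    "mitral_area_from_diameters",
    "forward_lvot_sv",
    "eoa_av_continuity",
    "ascending_aorta_area",
    "lvot_area",
]


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def mitral_area_from_diameters(d1: float, d2: float) -> float:
    """Mitral orifice area (cm²) from its two ellipse diameters (cm).

    The mitral orifice is approximated as an ellipse whose diameters are
    measured in the apical two- and four-chamber views.
    """
    if d1 <= 0 or d2 <= 0:
        raise DomainError(f"mitral diameters must be positive, got d1={d1}, d2={d2}")
    return math.pi * d1 * d2 / 4.0


def forward_lvot_sv(D_LVOT: float, VTI_LVOT: float) -> float:
    """Forward LVOT stroke volume (mL) from outflow-tract diameter (cm) and
    velocity-time integral (cm): A_LVOT · VTI = (πD²/4) · VTI."""
    if D_LVOT <= 0:
        raise DomainError(f"D_LVOT must be positive, got {D_LVOT}")
    if VTI_LVOT < 0:
        raise DomainError(f"VTI_LVOT must be non-negative, got {VTI_LVOT}")
    return math.pi * D_LVOT**2 / 4.0 * VTI_LVOT


def ascending_aorta_area(D_AO: float) -> float:
    """Ascending-aorta cross-sectional area (cm²) from its diameter (cm)."""
    if D_AO <= 0:
        raise DomainError(f"D_AO must be positive, got {D_AO}")
    return math.pi * D_AO**2 / 4.0


def lvot_area(D_LVOT: float) -> float:
    """LVOT cross-sectional area (cm²) from its diameter (cm)."""
    if D_LVOT <= 0:
        raise DomainError(f"D_LVOT must be positive, got {D_LVOT}")
    return math.pi * D_LVOT**2 / 4.0


def eoa_av_continuity(forward_sv: float, VTI_AO: float) -> float:
    """Aortic-valve effective orifice area (cm²) by the continuity method:
    stroke volume (mL) divided by the ascending-aorta VTI (cm)."""
    if forward_sv <= 0:
        raise DomainError(f"forward_sv must be positive, got {forward_sv}")
    if VTI_AO <= 0:
        raise DomainError(f"VTI_AO must be positive, got {VTI_AO}")
    return forward_sv / VTI_AO


# ---------------------------------------------------------------------------
# patient record
# ---------------------------------------------------------------------------

_MANDATORY = (
    "forward_lvot_sv",
    "T_EJ",
    "D_LVOT",
    "VTI_LVOT",
    "D_AO",
    "VTI_AO",
    "EOA_AV",
    "EDV",
    "ESV",
    "SBP",
    "DBP",
)


@dataclass
class PatientRecord:
    """One patient / time-point worth of non-invasive measurements.

    Either ``T`` (cardiac period, s) or ``HR`` (beats/min) must be given;
    the other is derived as T = 60/HR.  The mitral orifice may be given
    directly as ``EOA_MV`` or via the ellipse diameters ``d1``/``d2``
    (explicit EOA_MV wins when both are present).  Regurgitant orifice
    areas ``EOA_AR``/``EOA_MR`` are optional; their absence means the
    corresponding reverse valve branch is simply not built.
    """

    id: str
    forward_lvot_sv: float
    T_EJ: float
    D_LVOT: float
    VTI_LVOT: float
    D_AO: float
    VTI_AO: float
    EOA_AV: float
    EDV: float
    ESV: float
    SBP: float
    DBP: float
    T: Optional[float] = None
    HR: Optional[float] = None
    EOA_MV: Optional[float] = None
    d1: Optional[float] = None
    d2: Optional[float] = None
    EOA_AR: Optional[float] = None
    EOA_MR: Optional[float] = None

    def __post_init__(self) -> None:
        self._reconcile_period()
        self.validate()

    # -- period -------------------------------------------------------------
    def _reconcile_period(self) -> None:
        if self.T is None and self.HR is None:
            raise SchemaError("one of 'T' or 'HR' is required")
        if self.T is None:
            self.T = 60.0 / self.HR
        elif self.HR is None:
            self.HR = 60.0 / self.T
        else:
            if abs(self.T - 60.0 / self.HR) > 0.01 * self.T:
                raise ValidationError(
                    f"T={self.T} s and HR={self.HR} /min disagree by more than 1%"
                )

    # -- derived areas ------------------------------------------------------
    @property
    def A_LVOT(self) -> float:
        """LVOT cross-sectional area, cm²."""
        return lvot_area(self.D_LVOT)

    @property
    def A_AO(self) -> float:
        """Ascending-aorta cross-sectional area, cm²."""
        return ascending_aorta_area(self.D_AO)

    @property
    def mitral_area(self) -> float:
        """Effective mitral orifice area, cm² (explicit EOA_MV wins)."""
        if self.EOA_MV is not None:
            return self.EOA_MV
        if self.d1 is not None and self.d2 is not None:
            return mitral_area_from_diameters(self.d1, self.d2)
        raise SchemaError("record needs either 'EOA_MV' or both 'd1' and 'd2'")

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        for name in _MANDATORY:
            v = getattr(self, name)
            if v is None:
                raise SchemaError(f"mandatory field '{name}' is missing")
            if v <= 0:
                raise ValidationError(f"field '{name}' must be strictly positive, got {v}")
        for name in ("T", "d1", "d2", "EOA_MV", "EOA_AR", "EOA_MR"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidationError(f"field '{name}' must be strictly positive, got {v}")
        _ = self.mitral_area  # raises if neither EOA_MV nor (d1, d2)
        if self.T_EJ >= self.T:
            raise ValidationError(f"T_EJ={self.T_EJ} must be shorter than T={self.T}")
        if self.SBP <= self.DBP:
            raise ValidationError(f"SBP={self.SBP} must exceed DBP={self.DBP}")
        if self.EDV <= self.ESV:
            raise ValidationError(f"EDV={self.EDV} must exceed ESV={self.ESV}")
        if self.EOA_AV >= self.A_AO:
            raise ValidationError(
                f"EOA_AV={self.EOA_AV} cm² must be smaller than the ascending-aorta "
                f"area {self.A_AO:.4f} cm² (energy-loss denominator)"
            )
        if self.EOA_AR is not None and self.EOA_AR >= self.A_LVOT:
            raise ValidationError(
                f"EOA_AR={self.EOA_AR} cm² must be smaller than the LVOT area "
                f"{self.A_LVOT:.4f} cm²"
            )

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = {"schema_version": SCHEMA_VERSION}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v is not None:
                d[f.name] = v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PatientRecord":
        d = dict(d)
        d.pop("schema_version", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown field(s) in patient record: {sorted(unknown)}")
        if "id" not in d:
            raise SchemaError("mandatory field 'id' is missing")
        missing = [n for n in _MANDATORY if n not in d]
        if missing:
            raise SchemaError(f"mandatory field '{missing[0]}' is missing")
        return cls(**d)


def load_patient(path) -> PatientRecord:
    """Read and validate a patient record from a JSON file."""
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as e:
            raise SchemaError(f"{path} is not valid JSON: {e}") from e
    return PatientRecord.from_dict(d)


def save_patient(rec: PatientRecord, path) -> None:
    """Write a patient record as JSON (lossless float round-trip)."""
    with open(path, "w") as fh:
        json.dump(rec.to_dict(), fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# circulation parameters
# ---------------------------------------------------------------------------


@dataclass
class ElastanceParams:
    """Double-Hill time-varying elastance parameters for one heart chamber.

    ``tau1_frac``/``tau2_frac`` are fractions of the cardiac period T
    (the absolute time translations are τ_i = tau_i_frac · T).  The
    normalisation N = (E_max − E_min)/2 is always recomputed, never stored.
    """

    E_max: float  # mmHg/mL
    E_min: float  # mmHg/mL
    m1: float  # ascending gradient
    m2: float  # descending gradient
    tau1_frac: float  # ascending time translation, fraction of T
    tau2_frac: float  # descending time translation, fraction of T

    def __post_init__(self) -> None:
        if not (self.E_max > self.E_min > 0):
            raise ValidationError(
                f"need E_max > E_min > 0, got E_max={self.E_max}, E_min={self.E_min}"
            )
        if self.m1 <= 0 or self.m2 <= 0:
            raise ValidationError("elastance gradients m1, m2 must be positive")
        if not (0 < self.tau1_frac < self.tau2_frac < 1):
            raise ValidationError(
                f"need 0 < tau1_frac < tau2_frac < 1, got "
                f"{self.tau1_frac}, {self.tau2_frac}"
            )

    @property
    def N(self) -> float:
        """Elastance normalisation (E_max − E_min)/2, mmHg/mL."""
        return (self.E_max - self.E_min) / 2.0


def _lv_elastance() -> ElastanceParams:
    return ElastanceParams(E_max=2.1, E_min=0.06, m1=1.32, m2=27.4,
                           tau1_frac=0.269, tau2_frac=0.452)


def _la_elastance() -> ElastanceParams:
    return ElastanceParams(E_max=0.17, E_min=0.06, m1=1.32, m2=13.1,
                           tau1_frac=0.110, tau2_frac=0.18)


@dataclass
class CirculationParams:
    """All resistances, compliances, inertances and elastance constants of the
    closed-loop left-heart + systemic + pulmonary circuit.

    Defaults are the published reference values of the model; ``R_SA``,
    ``C_SAC`` and ``C_ao`` defaults are the *initial* values handed to the
    pressure optimisation, ``Q_MPV`` is the pulmonary-source amplitude fitted
    to the measured stroke volume, and ``R_ub`` is tuned so the upper-body
    branch carries 15% of systemic flow in the healthy baseline.
    Units: resistances mmHg·s/mL, compliances mL/mmHg, inertances mmHg·s²/mL,
    pressures mmHg, densities g/mL.
    """

    # systemic
    R_ao: float = 0.05
    C_ao: float = 0.5
    R_SV: float = 0.05
    C_SAC: float = 2.0
    R_SA: float = 0.8
    R_ub: float = 5.0  # placeholder; tune_upper_body() sets the 15%-split value
    R_pda: float = 0.05
    # pulmonary
    L_PV: float = 0.0005
    R_PV: float = 0.002
    R_PVC: float = 0.001
    C_PVC: float = 40.0
    L_PC: float = 0.0003
    R_PC: float = 0.21
    R_PA: float = 0.01
    C_PA: float = 4.0
    Q_MPV: float = 300.0  # mL/s, fitted per patient
    # boundary / constants
    P_CV0: float = 4.0
    rho_blood: float = 1.05  # g/mL
    M_MV: float = 0.53  # g/cm², mitral inertance constant
    # chambers
    elastance_LV: ElastanceParams = field(default_factory=_lv_elastance)
    elastance_LA: ElastanceParams = field(default_factory=_la_elastance)
    V0_LV: float = 10.0  # mL, unloaded LV volume (shifted to anchor EDV)
    V0_LA: float = 5.0  # mL, unloaded LA volume
    la_phase_frac: float = 0.85  # LA activation shift as fraction of T

    def __post_init__(self) -> None:
        for name in ("R_ao", "C_ao", "R_SV", "C_SAC", "R_SA", "R_ub", "R_pda",
                     "L_PV", "R_PV", "R_PVC", "C_PVC", "L_PC", "R_PC", "R_PA",
                     "C_PA", "rho_blood", "M_MV"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"parameter '{name}' must be strictly positive")
        if self.Q_MPV < 0:
            raise ValidationError("Q_MPV must be non-negative")
        if not (0.0 <= self.la_phase_frac < 1.0):
            raise ValidationError("la_phase_frac must lie in [0, 1)")

    def replace(self, **kwargs) -> "CirculationParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, ElastanceParams):
                v = dataclasses.asdict(v)
            d[f.name] = v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CirculationParams":
        d = dict(d)
        for key in ("elastance_LV", "elastance_LA"):
            if key in d and isinstance(d[key], dict):
                d[key] = ElastanceParams(**d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

_WAVE_FIELDS = ("t", "P_LV", "P_LA", "P_ao", "P_sa", "V_LV", "V_LA",
                "Q_AV", "Q_AR", "Q_MV", "Q_MR", "Q_PV", "Q_ub", "Q_sa")


@dataclass
class WaveformSet:
    """One steady-state cardiac cycle of pressures (mmHg), volumes (mL) and
    flows (mL/s) on a shared uniform time grid t ∈ [0, T]."""

    t: np.ndarray
    P_LV: np.ndarray
    P_LA: np.ndarray
    P_ao: np.ndarray
    P_sa: np.ndarray
    V_LV: np.ndarray
    V_LA: np.ndarray
    Q_AV: np.ndarray
    Q_AR: np.ndarray
    Q_MV: np.ndarray
    Q_MR: np.ndarray
    Q_PV: np.ndarray
    Q_ub: np.ndarray
    Q_sa: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.t)
        if n < 100:
            raise ValidationError(f"waveforms need ≥ 100 samples per cycle, got {n}")
        for name in _WAVE_FIELDS:
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (n,):
                raise ValidationError(f"waveform '{name}' length {arr.shape} != {n}")
        if abs(self.t[0]) > 1e-12:
            raise ValidationError("time grid must start at 0")
        if np.min(self.Q_AV) < -1e-6 or np.min(self.Q_MV) < -1e-6:
            raise ValidationError("forward valve flows must be non-negative (diode gating)")

    @property
    def T(self) -> float:
        """Cycle period, s (the grid spans one full cycle inclusively)."""
        return float(self.t[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({name: getattr(self, name) for name in _WAVE_FIELDS})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "WaveformSet":
        df = pd.read_csv(path)
        missing = [c for c in _WAVE_FIELDS if c not in df.columns]
        if missing:
            raise SchemaError(f"waveform CSV missing column(s): {missing}")
        return cls(**{c: df[c].to_numpy() for c in _WAVE_FIELDS})


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------


@dataclass
class FittedPatient:
    """Outcome of the two-stage patient-specific estimation.

    ``converged`` is only set when the stroke-volume residual is within 1% of
    the target and both pressure residuals are within 1 mmHg; otherwise the
    achieved residuals are reported as-is (non-convergence is a reported
    state, not an exception).
    """

    params: CirculationParams
    sv_error: float  # mL, model − target forward stroke volume
    sbp_error: float  # mmHg, model max P_ao − measured SBP
    dbp_error: float  # mmHg, model min P_ao − measured DBP
    n_cycles_to_steady: int
    converged: bool
    waveforms: Optional[WaveformSet] = None
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "sv_error": self.sv_error,
            "sbp_error": self.sbp_error,
            "dbp_error": self.dbp_error,
            "n_cycles_to_steady": self.n_cycles_to_steady,
            "converged": self.converged,
            "diagnostics": {k: v for k, v in self.diagnostics.items()
                            if isinstance(v, (int, float, str, bool, list))},
        }
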