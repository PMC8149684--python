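"""Global and local hemodynamic metrics.

Global circulatory/cardiac function: ejection fraction, LV workload (the
area enclosed by the pressure-volume loop, i.e. stroke work), systemic
arterial compliance (stroke volume over pulse pressure), transmitral E/A
velocity ratio, cycle pressure extrema and transvalvular gradients.

Local fluid dynamics summaries: time-averaged wall shear stress
TAWSS = (1/T)∫|τ|dt for a supplied wall-shear time series, and the vortex
sphericity index D2/D1 for supplied vortex length/width.  Both operate on
externally provided data — this package computes no 3-D flow fields.

All metrics are pure functions of their inputs.  Clinical classification
thresholds used by the convenience flags: EF < 41% reduced; SAC ≤ 1
mL/mmHg depressed; E/A outside 0.8–2 abnormal; mean aortic-valve gradient
> 40 mmHg severe stenosis; TAWSS outside 0.2–1.2 Pa abnormal for the LV;
sphericity index ≤ 2 non-normal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .errors import DomainError, ValidationError
from .records import WaveformSet
from .units import JOULE_PER_MMHG_ML

__all__ = ["PVLoop", "WallShearSeries", "ejection_fraction", "lv_workload",
           "systemic_arterial_compliance", "ea_ratio", "tawss",
           "sphericity_index", "pressure_summaries", "metrics_from_waveforms"]

EF_REDUCED_THRESHOLD = 0.41
SAC_DEPRESSED_THRESHOLD = 1.0  # mL/mmHg
EA_NORMAL_BAND = (0.8, 2.0)
MEAN_AV_PG_SEVERE = 40.0  # mmHg
TAWSS_NORMAL_BAND = (0.2, 1.2)  # Pa
SI_NORMAL_THRESHOLD = 2.0


@dataclass
class PVLoop:
    """A closed pressure-volume trajectory over one beat."""

    P: np.ndarray  # mmHg
    V: np.ndarray  # mL
    closed: bool = True

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.P.shape != self.V.shape or self.P.ndim != 1 or len(self.P) < 3:
            raise ValidationError("P and V must be equal-length 1-D arrays of length ≥ 3")

    @classmethod
    def from_waveforms(cls, waves: WaveformSet) -> "PVLoop":
        return cls(P=waves.P_LV, V=waves.V_LV, closed=True)


@dataclass
class WallShearSeries:
    """Instantaneous wall shear stress magnitude at one location."""

    t: np.ndarray  # s
    tau: np.ndarray  # Pa

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.t.shape != self.tau.shape or self.t.ndim != 1:
            raise ValidationError("t and tau must be equal-length 1-D arrays")
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError("wall-shear time grid must be strictly increasing")


def ejection_fraction(EDV: float, ESV: float) -> float:
    """EF = (EDV − ESV)/EDV; < 0.41 is conventionally classed as reduced."""
    if EDV <= 0 or ESV < 0:
        raise DomainError("volumes must be positive")
    if EDV <= ESV:
        raise DomainError(f"EDV={EDV} must exceed ESV={ESV}")
    return (EDV - ESV) / EDV


def lv_workload(loop: PVLoop) -> float:
    """LV stroke work in joules: the shoelace area |∮P dV| of the closed
    pressure-volume loop, converted from mmHg·mL (1 mmHg·mL = 1.33322e-4 J).
    """
    if not loop.closed:
        raise DomainError("workload requires a closed P-V loop")
    P, V = loop.P, loop.V
    if abs(P[0] - P[-1]) > 0 or abs(V[0] - V[-1]) > 0:
        P = np.append(P, P[0])
        V = np.append(V, V[0])
    area = 0.5 * np.sum(P[:-1] * np.diff(V) - V[:-1] * np.diff(P))
    # shoelace ∮P dV via Green's theorem; orientation-independent magnitude
    return float(abs(area)) * JOULE_PER_MMHG_ML


def systemic_arterial_compliance(forward_sv: float, SBP: float, DBP: float) -> float:
    """SAC = SV/(SBP − DBP) in mL/mmHg (stroke volume over pulse pressure).

    Reported unindexed; divide by body surface area for mL/m²/mmHg if an
    indexed value is wanted.
    """
    if forward_sv <= 0:
        raise DomainError("stroke volume must be positive")
    if SBP <= DBP:
        raise DomainError(f"zero or negative pulse pressure: SBP={SBP}, DBP={DBP}")
    return forward_sv / (SBP - DBP)


def ea_ratio(waves: WaveformSet, eoa_mv: float) -> dict:
    """Early (E) and atrial (A) transmitral peak velocities and their ratio.

    Transmitral velocity is Q_MV/EOA_MV (cm/s).  Peaks are local maxima of
    the diastolic inflow separated by at least 0.05·T; the earlier peak is
    E, the later A.  A fused or missing A wave yields ``ratio=None`` with
    the ``single_peak`` flag set.
    """
    if eoa_mv <= 0:
        raise DomainError("EOA_MV must be positive")
    v = waves.Q_MV / eoa_mv  # cm/s
    dt = waves.t[1] - waves.t[0]
    min_dist = max(1, int(round(0.05 * waves.T / dt)))
    floor = 0.02 * v.max() if v.max() > 0 else 0.0
    peaks, _ = find_peaks(v, distance=min_dist, height=floor)
    peaks = sorted(peaks, key=lambda i: v[i], reverse=True)[:2]
    peaks.sort()  # temporal order: E before A
    if len(peaks) < 2:
        e_peak = float(v[peaks[0]]) if peaks else float(v.max())
        return {"E_peak": e_peak, "A_peak": None, "ratio": None,
                "single_peak": True, "normal": None}
    e_peak, a_peak = float(v[peaks[0]]), float(v[peaks[1]])
    ratio = e_peak / a_peak
    return {"E_peak": e_peak, "A_peak": a_peak, "ratio": ratio,
            "single_peak": False,
            "normal": bool(EA_NORMAL_BAND[0] <= ratio <= EA_NORMAL_BAND[1])}


def tawss(series: WallShearSeries, T: float) -> float:
    """Time-averaged wall shear stress (Pa): (1/T)·∫|τ| dt by the trapezoidal
    rule over a series spanning [0, T]."""
    if T <= 0:
        raise DomainError("period must be positive")
    if series.t[0] < -1e-12 or series.t[-1] > T * (1 + 1e-12):
        raise DomainError(f"wall-shear samples must lie within [0, {T}]")
    return float(np.trapezoid(np.abs(series.tau), series.t) / T)


def sphericity_index(D2_length: float, D1_width: float) -> float:
    """Vortex sphericity index D2/D1 (length over width); values > 2 are
    conventionally normal for the LV diastolic vortex."""
    if D2_length <= 0 or D1_width <= 0:
        raise DomainError("vortex dimensions must be positive")
    return D2_length / D1_width


def pressure_summaries(waves: WaveformSet) -> dict:
    """Cycle pressure extrema and phase-restricted transvalvular gradients.

    The aortic-valve gradient is max over the ejection phase (Q_AV > 0) of
    P_LV − P_ao; the transmitral gradient is max over the filling phase
    (Q_MV > 0) of P_LA − P_LV; both are non-negative by construction.  The
    mean aortic gradient is the ejection-phase time average.
    """
    if len(waves.t) == 0:
        raise DomainError("empty waveform")
    eject = waves.Q_AV > 1e-6
    fill = waves.Q_MV > 1e-6
    av_pg = np.maximum(waves.P_LV - waves.P_ao, 0.0)
    mv_pg = np.maximum(waves.P_LA - waves.P_LV, 0.0)
    out = {
        "max_P_LA": float(waves.P_LA.max()),
        "max_P_LV": float(waves.P_LV.max()),
        "max_P_ao": float(waves.P_ao.max()),
        "min_P_ao": float(waves.P_ao.min()),
        "max_AV_PG": float(av_pg[eject].max()) if eject.any() else 0.0,
        "max_transmitral_PG": float(mv_pg[fill].max()) if fill.any() else 0.0,
        "mean_AV_PG": float(av_pg[eject].mean()) if eject.any() else 0.0,
    }
    out["severe_AS"] = bool(out["mean_AV_PG"] > MEAN_AV_PG_SEVERE)
    return out


def doppler_av_gradient(waves: WaveformSet, eoa_av: float) -> float:
    """Simplified-Bernoulli estimate 4·v_max² (mmHg) of the peak aortic
    gradient from the peak transvalvular velocity v = Q_AV/EOA_AV (m/s),
    reported alongside the instantaneous circuit pressure difference."""
    if eoa_av <= 0:
        raise DomainError("EOA_AV must be positive")
    v_max_m_s = waves.Q_AV.max() / eoa_av / 100.0
    return float(4.0 * v_max_m_s**2)


def metrics_from_waveforms(waves: WaveformSet, eoa_mv: float,
                           eoa_av: Optional[float] = None,
                           forward_sv: Optional[float] = None) -> dict:
    """Bundle of the global metrics computed from one steady cycle."""
    edv = float(waves.V_LV.max())
    esv = float(waves.V_LV.min())
    sv = forward_sv if forward_sv is not None else float(
        np.trapezoid(waves.Q_AV, waves.t))
    sbp = float(waves.P_ao.max())
    dbp = float(waves.P_ao.min())
    ef = ejection_fraction(edv, esv)
    sac = systemic_arterial_compliance(sv, sbp, dbp) if sv > 0 and sbp > dbp else None
    out = {
        "EDV": edv,
        "ESV": esv,
        "forward_sv": sv,
        "EF": ef,
        "EF_reduced": bool(ef < EF_REDUCED_THRESHOLD),
        "lv_workload_J": lv_workload(PVLoop.from_waveforms(waves)),
        "SAC": sac,
        "SAC_depressed": bool(sac <= SAC_DEPRESSED_THRESHOLD) if sac is not None else None,
        "SAC_formula": "forward_sv / (SBP - DBP)",
        "ea": ea_ratio(waves, eoa_mv),
    }
    out.update(pressure_summaries(waves))
    if eoa_av is not None:
        out["max_AV_PG_doppler_4v2"] = doppler_av_gradient(waves, eoa_av)
    return out
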