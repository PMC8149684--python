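"""Hand-rolled builders shared across test modules."""

import numpy as np

from lumpedheart.records import PatientRecord, WaveformSet


def make_record(**overrides):
    """A physiologically sensible baseline record, overridable per test."""
    base = dict(
        id="p1", forward_lvot_sv=70.0, HR=70.0, T_EJ=0.30,
        D_LVOT=2.0, VTI_LVOT=22.28, D_AO=3.0, VTI_AO=46.7,
        EOA_AV=1.5, EOA_MV=4.0, EDV=130.0, ESV=60.0, SBP=120.0, DBP=80.0,
    )
    base.update(overrides)
    return PatientRecord(**base)


def make_waves(t, **columns):
    """A WaveformSet whose unspecified columns are zeros (for metric tests
    that only exercise a subset of the channels)."""
    n = len(t)
    fields = dict(
        P_LV=np.zeros(n), P_LA=np.zeros(n), P_ao=np.zeros(n), P_sa=np.zeros(n),
        V_LV=np.zeros(n), V_LA=np.zeros(n), Q_AV=np.zeros(n), Q_AR=np.zeros(n),
        Q_MV=np.zeros(n), Q_MR=np.zeros(n), Q_PV=np.zeros(n), Q_ub=np.zeros(n),
        Q_sa=np.zeros(n),
    )
    fields.update(columns)
    return WaveformSet(t=np.asarray(t, dtype=float), **fields)
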