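"""Unit conventions and conversion constants.

The canonical internal unit system follows clinical convention:
pressure in mmHg, volume in mL, time in s, length in cm.  Resistances are
therefore mmHg·s/mL, compliances mL/mmHg and inertances mmHg·s²/mL.
Dynamic-pressure (Bernoulli) terms of the valve models are evaluated in
CGS (dyn/cm², with blood density in g/mL = g/cm³) and converted to mmHg
with the single constant below; keeping one declared conversion avoids
silent SI/CGS mix-ups.
"""

# 1 mmHg expressed in dyn/cm² (CGS pressure).
DYN_CM2_PER_MMHG: float = 1333.22

# 1 mmHg·mL expressed in joules (pressure-volume work).
JOULE_PER_MMHG_ML: float = 1.33322e-4

# 1 mmHg expressed in pascal.
PA_PER_MMHG: float = 133.322

# Blood density, g/mL (1050 kg/m³).
BLOOD_DENSITY_G_PER_ML: float = 1.05
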