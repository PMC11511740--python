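"""Unit conversions used throughout the package.

Internally everything is SI (m, s, Pa, m^3/s).  On-disk network tables and
reported biomarkers use the clinical units of the field: mm, kPa, mmHg,
ml/min, and the conventional 1e10 Pa s/m^3 / 1e-10 m^3/Pa scales for
peripheral resistance and compliance.
"""

MMHG_PA = 133.322387415

#: scale factor for peripheral vascular resistance columns (1e10 Pa s / m^3)
PVR_SCALE = 1e10
#: scale factor for peripheral vascular compliance columns (1e-10 m^3 / Pa)
PVC_SCALE = 1e-10


def pa_to_mmhg(p):
    return p / MMHG_PA


def mmhg_to_pa(p):
    return p * MMHG_PA


def m3s_to_mlmin(q):
    """m^3/s -> ml/min."""
    return q * 6.0e7


def mlmin_to_m3s(q):
    return q / 6.0e7


def lmin_to_m3s(q):
    """litres/min -> m^3/s (cardiac output tables)."""
    return q * 1e-3 / 60.0
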