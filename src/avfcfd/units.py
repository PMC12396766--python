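"""Unit conversions.

Internal computations are SI (m, s, Pa, kg).  Public interfaces speak the
units the field reports: mm for diameters and arc length, µm for voxel
spacing, mL/min for flow rates, bpm for heart rate.
"""

MM_PER_M = 1e3
UM_PER_M = 1e6
UM_PER_MM = 1e3

#: 1 m³/s expressed in mL/min.
ML_MIN_PER_M3_S = 6.0e7


def mm_to_m(x):
    return x / MM_PER_M


def m_to_mm(x):
    return x * MM_PER_M


def um_to_mm(x):
    return x / UM_PER_MM


def mm_to_um(x):
    return x * UM_PER_MM


def um_to_m(x):
    return x / UM_PER_M


def m3s_to_mlmin(q):
    return q * ML_MIN_PER_M3_S


def mlmin_to_m3s(q):
    return q / ML_MIN_PER_M3_S


def bpm_to_hz(rate):
    return rate / 60.0


def bpm_to_period_s(rate):
    return 60.0 / rate
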