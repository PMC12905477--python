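"""Unit conventions.

All internal computation is in CGS: lengths in cm, flow in mL/s, pressure in
barye (g cm^-1 s^-2, gauge).  Pressures cross the mmHg boundary only at I/O.
"""

MMHG_TO_CGS = 1333.22
CGS_TO_MMHG = 1.0 / MMHG_TO_CGS


def mmhg_to_cgs(p_mmhg):
    return p_mmhg * MMHG_TO_CGS


def cgs_to_mmhg(p_cgs):
    return p_cgs * CGS_TO_MMHG
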