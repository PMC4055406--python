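"""Unit conventions and conversions.

All internal computation is done in CGS units (cm, g, s, dyn):

===================  =======================  =========================
quantity             internal (CGS)           reporting
===================  =======================  =========================
pressure             dyn·cm⁻²                 mmHg
flow                 cm³·s⁻¹ (= ml·s⁻¹)       ml·s⁻¹
resistance           dyn·s·cm⁻⁵               mmHg·s·ml⁻¹
inertance            g·cm⁻⁴                   mmHg·s²·ml⁻¹
compliance           cm⁵·dyn⁻¹                ml·mmHg⁻¹
===================  =======================  =========================
"""

MMHG = 1333.22  # dyn·cm⁻² per mmHg


def pressure_to_mmhg(p_cgs: float) -> float:
    return p_cgs / MMHG


def pressure_from_mmhg(p_mmhg: float) -> float:
    return p_mmhg * MMHG


def resistance_to_mmhg(r_cgs: float) -> float:
    """dyn·s·cm⁻⁵ → mmHg·s·ml⁻¹."""
    return r_cgs / MMHG


def resistance_from_mmhg(r_mmhg: float) -> float:
    return r_mmhg * MMHG


def inertance_to_mmhg(l_cgs: float) -> float:
    """g·cm⁻⁴ → mmHg·s²·ml⁻¹."""
    return l_cgs / MMHG


def inertance_from_mmhg(l_mmhg: float) -> float:
    return l_mmhg * MMHG


def compliance_to_mmhg(c_cgs: float) -> float:
    """cm⁵·dyn⁻¹ → ml·mmHg⁻¹."""
    return c_cgs * MMHG


def compliance_from_mmhg(c_mmhg: float) -> float:
    return c_mmhg / MMHG
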