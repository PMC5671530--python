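"""Unit conversion constants and helpers.

Internal conventions:

* lengths in metres, stresses/pressures in MPa, concentrations in µM,
  diffusivities in cm²/s at the user surface (converted to m²/s internally).
* suction levels are specified as positive mmHg magnitudes and converted
  exactly (1 mmHg = 133.322 Pa), not via the paper's rounded MPa aliases.
"""

from __future__ import annotations

#: Pa per mmHg (conventional definition, exact for our purposes).
PA_PER_MMHG = 133.322

#: mmHg per MPa.
MMHG_PER_MPA = 1.0e6 / PA_PER_MMHG

#: µM of O2 per (ml O2/ml) volume fraction. 1 ml of ideal gas at STP is
#: 1/22414 mol, so 1 ml O2 per ml = (1000/22414) mol/L = 44.615 mM = 44615 µM.
UM_PER_ML_O2_PER_ML = 1000.0 / 22414.0 * 1.0e6

CM = 1.0e-2
MM = 1.0e-3
UM = 1.0e-6


def mmhg_to_mpa(p_mmhg: float) -> float:
    """Convert a pressure magnitude from mmHg to MPa (exact factor)."""
    return p_mmhg * PA_PER_MMHG * 1.0e-6


def mpa_to_mmhg(p_mpa: float) -> float:
    """Convert MPa to mmHg."""
    return p_mpa * MMHG_PER_MPA


def solubility_drift_scale(s_ml_o2_per_ml_mmhg: float) -> float:
    """Concentration-equivalent of an equivalent-pressure-stress field.

    Returns the factor k such that ``k * p[MPa]`` is the µM concentration
    equivalent ``s * p`` appearing in the extended Fick's law drift term:
    solubility (ml O2 · ml⁻¹ · mmHg⁻¹) times pressure (converted MPa→mmHg),
    with the resulting O2 volume fraction expressed in µM.
    """
    return s_ml_o2_per_ml_mmhg * MMHG_PER_MPA * UM_PER_ML_O2_PER_ML
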