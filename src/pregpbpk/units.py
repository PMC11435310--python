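"""Canonical internal units and conversion helpers.

The whole package works in mass µg, volume mL, time h, concentration
µg/mL.  Molar quantities (interaction constants are µM) are converted
through the molecular weight.
"""

#: (mg/s per mg enzyme) * (mg enzyme) / (µg/mL) -> L/h
VMAX_PER_KM_TO_L_PER_H = 3600.0

L_PER_H_TO_ML_PER_H = 1000.0
CM2_PER_S_TO_CM2_PER_H = 3600.0
CM_PER_S_TO_CM_PER_H = 3600.0
SECONDS_PER_HOUR = 3600.0
MG_TO_UG = 1000.0


def ug_per_ml_to_um(conc_ug_ml: float, molecular_weight: float) -> float:
    """µg/mL -> µM (MW in g/mol)."""
    return conc_ug_ml / molecular_weight * 1000.0


def um_to_ug_per_ml(conc_um: float, molecular_weight: float) -> float:
    """µM -> µg/mL (MW in g/mol)."""
    return conc_um * molecular_weight / 1000.0
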