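"""Tissue-to-plasma partition coefficients (Kp) and steady-state volume of
distribution.

Implements the Rodgers-Rowland method family in the single-equation
(Lukacova-unified) form: one expression across ionization classes in which
neutral species partition into tissue water and lipids and bind
extracellular proteins, while the cation of a strong base (pKa > 7)
additionally binds acidic phospholipids with an affinity back-calculated
from the blood-to-plasma ratio.  Adipose neutral lipid is treated as
olive oil (logD_vo = 1.115 logP - 1.35).

All Kp values are total-tissue to total-plasma ratios at distribution
equilibrium; Kp = Kpu * fup.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import DrugParameters
from .physiology import BLOOD_TISSUES, Physiology, TissueCompartment

__all__ = ["KpSet", "compute_kp", "compute_kp_set", "compute_vss"]

PH_PLASMA = 7.4
PH_INTRACELL = 7.0
PH_RBC = 7.22

#: plasma and red-blood-cell composition used on the reference side
PLASMA = {"f_nl": 0.0035, "f_np": 0.00225}
RBC = {"f_iw": 0.63, "f_nl": 0.0017, "f_np": 0.0029, "ap_mg_g": 0.5}

#: standard hematocrit behind the measured blood:plasma ratio
HCT_REFERENCE = 0.45


class CompositionError(ValueError):
    """Tissue composition missing for Kp prediction."""


@dataclass(frozen=True)
class KpSet:
    drug: str
    method: str
    values: dict[str, float]
    vss_per_kg: float

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.values.values()):
            raise ValueError("all Kp values must be positive")
        if self.vss_per_kg <= 0:
            raise ValueError("vss_per_kg must be positive")


def _ionized_ratio(drug: DrugParameters, ph: float) -> float:
    """[ionized]/[neutral] at the given pH."""
    if drug.ionization_class == "monoprotic_base":
        return 10.0 ** (drug.pka - ph)
    if drug.ionization_class == "monoprotic_acid":
        return 10.0 ** (ph - drug.pka)
    return 0.0


def _is_strong_base(drug: DrugParameters) -> bool:
    return drug.ionization_class == "monoprotic_base" and drug.pka >= 7.0


def _lipid_term(p_nl: float, f_nl: float, f_np: float) -> float:
    return p_nl * f_nl + (0.3 * p_nl + 0.7) * f_np


def _ka_ap(drug: DrugParameters, fup: float) -> float:
    """Acidic-phospholipid association constant of the cation,
    back-calculated from blood-cell partitioning."""
    p = 10.0 ** drug.log_p
    x_p = _ionized_ratio(drug, PH_PLASMA)
    x_bc = _ionized_ratio(drug, PH_RBC)
    kpu_bc = (drug.blood_plasma_ratio - (1.0 - HCT_REFERENCE)) / (HCT_REFERENCE * fup)
    water = RBC["f_iw"] * (1.0 + x_bc) / (1.0 + x_p)
    lipid = _lipid_term(p, RBC["f_nl"], RBC["f_np"]) / (1.0 + x_p)
    ka = (kpu_bc - water - lipid) * (1.0 + x_p) / (RBC["ap_mg_g"] * x_bc)
    return max(ka, 0.0)


def compute_kp(drug: DrugParameters, tissue: TissueCompartment,
               fup: float | None = None) -> float:
    """Kp of one tissue by the Rodgers-Rowland single-equation method.

    ``fup`` overrides the drug's plasma fraction unbound (used by the
    pregnancy albumin-dilution adjustment).
    """
    if tissue.composition is None:
        raise CompositionError(f"no composition data for tissue {tissue.name!r}")
    c = tissue.composition
    if fup is None:
        fup = drug.fraction_unbound_plasma

    p = 10.0 ** drug.log_p
    p_nl = 10.0 ** (1.115 * drug.log_p - 1.35) if tissue.name == "adipose" else p
    x_p = _ionized_ratio(drug, PH_PLASMA)
    x_iw = _ionized_ratio(drug, PH_INTRACELL)

    kpu = (c["f_ew"]
           + c["f_iw"] * (1.0 + x_iw) / (1.0 + x_p)
           + _lipid_term(p_nl, c["f_nl"], c["f_np"]) / (1.0 + x_p))
    if _is_strong_base(drug):
        # Ka_AP is a molecular constant: derive it once from the measured
        # B:P at the drug's reference fup, not at any override value
        ka_ap = _ka_ap(drug, drug.fraction_unbound_plasma)
        kpu += ka_ap * c["ap_mg_g"] * x_iw / (1.0 + x_p)
    else:
        plasma_lipid = _lipid_term(p, PLASMA["f_nl"], PLASMA["f_np"]) / (1.0 + x_p)
        kpu += c["ra"] * max(1.0 / fup - 1.0 - plasma_lipid, 0.0)
    return kpu * fup


def blood_cell_kp(drug: DrugParameters, hematocrit: float = HCT_REFERENCE) -> float:
    """Blood-cell:plasma ratio implied by the measured B:P ratio."""
    kp = (drug.blood_plasma_ratio - (1.0 - hematocrit)) / hematocrit
    return max(kp, 1e-3)


def compute_kp_set(drug: DrugParameters, phys: Physiology,
                   kp_scale: float = 1.0, fup: float | None = None,
                   method: str = "lukacova_rodgers_single") -> KpSet:
    """Predict Kp for every tissue and aggregate whole-body Vss.

    rest-of-body takes the volume-weighted mean of the computed tissues;
    a global ``kp_scale`` (default 1.0) lets the disposition be calibrated
    to a known volume of distribution, as is common PBPK practice.
    """
    if method != "lukacova_rodgers_single":
        raise ValueError(f"unknown Kp method {method!r}")
    values: dict[str, float] = {}
    weighted = total_v = 0.0
    for t in phys.tissues:
        if t.name in BLOOD_TISSUES or t.name == "rest_of_body":
            continue
        kp = compute_kp(drug, t, fup=fup) * kp_scale
        values[t.name] = kp
        weighted += kp * t.volume
        total_v += t.volume
    values["rest_of_body"] = weighted / total_v
    kps = KpSet(drug=drug.name, method=method, values=values, vss_per_kg=1.0)
    vss = compute_vss(kps, phys, drug)
    return KpSet(drug=drug.name, method=method, values=values, vss_per_kg=vss)


def compute_vss(kps: KpSet, phys: Physiology, drug: DrugParameters) -> float:
    """Steady-state volume of distribution (plasma-referenced), L/kg:
    Vss = (plasma volume + blood-cell volume * Kp_bc + sum Kp_t V_t) / BW."""
    missing = [t.name for t in phys.tissues
               if t.name not in BLOOD_TISSUES and t.name not in kps.values]
    if missing:
        raise ValueError(f"Kp missing for tissues: {missing}")
    v_cells = phys.blood_volume - phys.plasma_volume
    total = phys.plasma_volume + v_cells * blood_cell_kp(drug, phys.hematocrit)
    for t in phys.tissues:
        if t.name in BLOOD_TISSUES:
            continue
        total += kps.values[t.name] * t.volume
    return total / phys.body_weight
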