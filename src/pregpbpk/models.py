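"""Calibrated whole-body models for the built-in drugs.

Standard PBPK model building practice is followed: the Rodgers-Rowland
Kp predictions are scaled by a single global factor so that whole-body
Vss matches the drug's compartmental volume-of-distribution estimate,
and the enzyme amounts are scaled so that the linear-range (well-stirred)
hepatic clearance plus renal clearance reproduces the compartmental total
plasma clearance, with the reported fm percentages fixing the split
between pathways (the non-enzymatic remainder is assigned to renal
clearance).  Both calibrations are carried out once on the standard adult
male and reused unchanged across populations, so sex and pregnancy
effects are purely physiological.

The pregnancy model replaces each UGT pathway's intrinsic clearance with
the reported gestational-week trajectory and, by default, dilutes plasma
albumin binding with gestation.
"""

from __future__ import annotations

from dataclasses import replace

from .absorption import build_gi_tract
from .engine import PBPKModel, assemble_model
from .parameters import (DrugProfile, abundance_from_clint, gestational_clint,
                         load_profile, scaled_intrinsic_clearance)
from .partition import compute_kp_set
from .physiology import (Physiology, build_physiology, build_pregnant_physiology,
                         gfr_factor, pregnancy_fraction_unbound)

__all__ = ["build_model", "build_physiology_for", "raw_vss_per_kg"]

POPULATIONS = ("adult_male", "adult_female", "pregnant")

#: reference adult used for all disposition calibrations
_CAL_SEX, _CAL_BW = "male", 70.0


def build_physiology_for(population: str, gestational_week: float = 0.0,
                         body_weight: float | None = None,
                         age: float = 30.0) -> Physiology:
    if population not in POPULATIONS:
        raise ValueError(f"unknown population {population!r}")
    if population == "adult_male":
        return build_physiology("male", body_weight, age)
    base = build_physiology("female", body_weight, age)
    if population == "adult_female":
        return base
    if gestational_week <= 0:
        raise ValueError("pregnant population requires gestational_week > 0")
    return build_pregnant_physiology(base, gestational_week)


def raw_vss_per_kg(drug_name: str) -> float:
    """Uncalibrated Rodgers-Rowland Vss (L/kg) in the standard adult male."""
    profile = load_profile(drug_name)
    phys = build_physiology(_CAL_SEX, _CAL_BW)
    return compute_kp_set(profile.drug, phys).vss_per_kg


def _hepatic_blood_flow(phys: Physiology) -> float:
    """Total liver inflow (hepatic artery + portal), L/h of blood."""
    return sum(phys.tissue(n).blood_flow for n in ("liver", "gut", "spleen"))


def _calibrate_enzymes(profile: DrugProfile, cal_phys: Physiology):
    """Enzyme abundances and renal clearance reproducing the compartmental
    total plasma clearance in the calibration physiology (well-stirred
    inversion in the linear range)."""
    drug = profile.drug
    cl_total = profile.total_clearance_l_per_h
    if cl_total is None:
        return profile.enzymes, 0.0, 1.0
    fm_total = profile.fm_total
    cl_renal = cl_total * (1.0 - fm_total / 100.0)
    cl_hep_blood = (cl_total - cl_renal) / drug.blood_plasma_ratio
    q_h = _hepatic_blood_flow(cal_phys)
    if cl_hep_blood >= q_h:
        raise ValueError("hepatic clearance target exceeds liver blood flow")
    fu_b = drug.fraction_unbound_plasma / drug.blood_plasma_ratio
    clint_target = q_h * cl_hep_blood / (fu_b * (q_h - cl_hep_blood))

    liver = [e for e in profile.enzymes if e.location == "liver"]
    enzymes = []
    if all(e.abundance is not None for e in liver):
        # reported per-enzyme Clint: scale all pathways by one factor
        clint_printed = sum(scaled_intrinsic_clearance(e) for e in liver)
        s = clint_target / clint_printed
        for e in liver:
            enzymes.append(replace(e, abundance=e.abundance * s))
    else:
        # split the calibrated Clint by the fm percentages
        s = 1.0
        fm_liver = sum(e.fm for e in liver)
        for e in liver:
            clint_e = clint_target * e.fm / fm_liver
            enzymes.append(replace(e, abundance=abundance_from_clint(e.vmax, e.km,
                                                                     clint_e)))
    for e in profile.enzymes:
        if e.location != "gut":
            continue
        if profile.gut_fg_target is None:
            raise ValueError(f"gut enzyme {e.enzyme} needs a gut_fg_target anchor")
        from .engine import VILLOUS_FLOW_FRACTION
        q_v = cal_phys.tissue("gut").blood_flow * VILLOUS_FLOW_FRACTION
        clint_gut = q_v * (1.0 / profile.gut_fg_target - 1.0) / fu_b
        enzymes.append(replace(e, abundance=abundance_from_clint(e.vmax, e.km,
                                                                 clint_gut)))
    return tuple(enzymes), cl_renal, s


def _pregnant_enzymes(profile: DrugProfile, enzymes, s: float, ga: float):
    """Swap each tabulated pathway's clearance for its gestational value,
    keeping the adult calibration factor."""
    out = []
    for e in enzymes:
        table = profile.gestational_clint.get(e.enzyme)
        if table is not None and e.location == "liver":
            clint_ga = gestational_clint(table, ga) * s
            out.append(replace(e, abundance=abundance_from_clint(e.vmax, e.km,
                                                                 clint_ga)))
        else:
            out.append(e)
    return tuple(out)


def build_model(drug: str = "LTG", population: str = "adult_male",
                gestational_week: float = 0.0,
                body_weight: float | None = None, age: float = 30.0,
                albumin_shift: bool = True, stomach_transit_h: float = 0.5,
                biorelevant: bool = True, kp_scale: float | None = None) -> PBPKModel:
    """Assemble a calibrated PBPK model for a built-in (or file) drug profile.

    ``kp_scale=None`` calibrates the Kp scalar to the drug's Vss anchor on
    the standard adult male; pass 1.0 for the raw Rodgers-Rowland
    prediction.  ``albumin_shift`` applies the gestational fraction-unbound
    adjustment (ignored outside pregnancy).
    """
    profile = load_profile(drug)
    cal_phys = build_physiology(_CAL_SEX, _CAL_BW)

    if kp_scale is None:
        if profile.vss_target_l_per_kg is not None:
            raw = compute_kp_set(profile.drug, cal_phys).vss_per_kg
            kp_scale = profile.vss_target_l_per_kg / raw
        else:
            kp_scale = 1.0

    enzymes, cl_renal, s = _calibrate_enzymes(profile, cal_phys)

    phys = build_physiology_for(population, gestational_week, body_weight, age)
    fup = None
    if population == "pregnant" and albumin_shift:
        fup = pregnancy_fraction_unbound(profile.drug.fraction_unbound_plasma,
                                         gestational_week)
    if population == "pregnant":
        enzymes = _pregnant_enzymes(profile, enzymes, s, gestational_week)
        cl_renal = cl_renal * gfr_factor(gestational_week)

    kps = compute_kp_set(profile.drug, phys, kp_scale=kp_scale, fup=fup)
    gi = build_gi_tract(profile.drug, phys, stomach_transit_h=stomach_transit_h,
                        biorelevant=biorelevant)
    return assemble_model(profile.drug, phys, kps, enzymes=enzymes,
                          renal_clearance=cl_renal, gi=gi, fraction_unbound=fup,
                          interactions=profile.interactions)
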