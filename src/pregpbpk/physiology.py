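"""Whole-body physiologies: adult male, adult female and pregnant female.

Organ volumes and blood flows come from bundled adult reference tables
(ICRP-style reference persons) scaled to body weight (volumes ~ BW, flows
~ BW^0.75).  The pregnant physiology applies published-style gestational
functions: body weight gain, plasma-volume expansion, haemodilution,
cardiac-output and GFR rise, adipose and utero-placental growth.  Fetal
sub-compartments are not resolved; the conceptus volume is lumped into the
reproductive compartment.
"""

from __future__ import annotations

import importlib.resources
import io
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "TissueCompartment",
    "Physiology",
    "build_physiology",
    "build_pregnant_physiology",
    "pregnancy_fraction_unbound",
    "tissue_composition_table",
    "export_physiology",
    "import_physiology",
]

#: reference body weights (kg) and cardiac outputs (L/h) behind the bundled tables
REFERENCE = {
    "male": {"body_weight": 73.0, "cardiac_output": 390.0, "hematocrit": 0.45,
             "gfr": 7.5},
    "female": {"body_weight": 60.0, "cardiac_output": 354.0, "hematocrit": 0.40,
               "gfr": 6.6},
}

#: mean whole-body density, kg/L
BODY_DENSITY = 1.05

BLOOD_TISSUES = ("arterial_blood", "venous_blood")


def _read_data_csv(name: str) -> pd.DataFrame:
    text = (importlib.resources.files("pregpbpk.data") / name).read_text()
    return pd.read_csv(io.StringIO(text), comment="#")


def tissue_composition_table() -> pd.DataFrame:
    """Bundled Rodgers-Rowland tissue composition data (indexed by tissue)."""
    return _read_data_csv("tissue_composition.csv").set_index("tissue")


@dataclass(frozen=True)
class TissueCompartment:
    name: str
    volume: float  # L
    blood_flow: float  # L/h
    composition: dict | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError(f"{self.name}: volume must be positive")
        if self.blood_flow < 0:
            raise ValueError(f"{self.name}: blood_flow must be >= 0")


@dataclass(frozen=True)
class Physiology:
    sex: str
    body_weight: float  # kg
    gestational_age: float  # weeks, 0 = non-pregnant
    tissues: tuple[TissueCompartment, ...]
    cardiac_output: float  # L/h
    glomerular_filtration_rate: float  # L/h
    hematocrit: float
    plasma_volume: float  # L

    def __post_init__(self) -> None:
        flows = sum(t.blood_flow for t in self.tissues
                    if t.name not in BLOOD_TISSUES and t.name != "lung")
        if abs(flows - self.cardiac_output) > 1e-6 * self.cardiac_output:
            raise ValueError("cardiac output must equal the sum of non-lung "
                             f"tissue flows ({flows:.3f} vs {self.cardiac_output:.3f})")
        volume = sum(t.volume for t in self.tissues)
        expected = self.body_weight / BODY_DENSITY
        if abs(volume - expected) > 0.10 * expected:
            raise ValueError("tissue volumes inconsistent with body weight "
                             f"({volume:.2f} L vs {expected:.2f} L expected)")

    def tissue(self, name: str) -> TissueCompartment:
        for t in self.tissues:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def blood_volume(self) -> float:
        return self.tissue("arterial_blood").volume + self.tissue("venous_blood").volume


def build_physiology(sex: str, body_weight: float | None = None,
                     age: float = 30.0) -> Physiology:
    """Adult physiology scaled to body weight (volumes ~ BW, flows ~ BW^0.75).

    Defaults: 70 kg male, 60 kg female, age 30.
    """
    if sex not in REFERENCE:
        raise ValueError(f"unsupported sex {sex!r}")
    if not 18.0 <= age <= 65.0:
        raise ValueError(f"age {age} outside the supported adult range 18-65")
    ref = REFERENCE[sex]
    if body_weight is None:
        body_weight = 70.0 if sex == "male" else 60.0
    if not 40.0 <= body_weight <= 150.0:
        raise ValueError(f"body weight {body_weight} outside 40-150 kg")

    table = _read_data_csv("reference_physiology.csv")
    table = table[table["sex"] == sex]
    comp = tissue_composition_table()
    co = ref["cardiac_output"] * (body_weight / ref["body_weight"]) ** 0.75
    tissues = []
    for _, row in table.iterrows():
        name = row["tissue"]
        volume = row["volume_fraction"] * body_weight
        flow = row["flow_fraction"] * co
        if name == "lung":
            flow = co  # lung is in series and carries the whole cardiac output
        composition = comp.loc[name].to_dict() if name in comp.index else None
        tissues.append(TissueCompartment(name, volume, flow, composition))
    gfr = ref["gfr"] * (body_weight / ref["body_weight"]) ** 0.75
    plasma = (table.set_index("tissue").loc[list(BLOOD_TISSUES), "volume_fraction"].sum()
              * body_weight * (1.0 - ref["hematocrit"]))
    return Physiology(sex=sex, body_weight=body_weight, gestational_age=0.0,
                      tissues=tuple(tissues), cardiac_output=co,
                      glomerular_filtration_rate=gfr,
                      hematocrit=ref["hematocrit"], plasma_volume=plasma)


# ---------------------------------------------------------------------------
# gestational functions (fraction-of-term parameterisation, term = 40 weeks)

def gestational_weight_gain(ga: float) -> float:
    """Maternal weight gain (kg); 12.5 kg at term."""
    return 12.5 * (ga / 40.0) ** 1.7


def plasma_volume_factor(ga: float) -> float:
    """Plasma-volume expansion factor; +48% at term."""
    return 1.0 + 0.48 * (ga / 40.0) ** 1.3


def gfr_factor(ga: float) -> float:
    """Glomerular filtration rise; +50% at term."""
    return 1.0 + 0.50 * (ga / 40.0) ** 0.8


def hematocrit_factor(ga: float) -> float:
    """Haemodilution; hematocrit falls ~12% by term."""
    return 1.0 - 0.12 * (ga / 40.0)


def albumin_factor(ga: float) -> float:
    """Serum albumin relative to non-pregnant; ~-22% at term."""
    return 1.0 - 0.22 * (ga / 40.0) ** 1.1


def pregnancy_fraction_unbound(fup: float, ga: float) -> float:
    """Fraction unbound in plasma after gestational albumin dilution.

    Linear-binding model: bound/free scales with the albumin concentration,
    so fup' = fup / (fup + (1 - fup) * albumin_ratio).
    """
    ratio = albumin_factor(ga)
    return fup / (fup + (1.0 - fup) * ratio)


def build_pregnant_physiology(base: Physiology, ga: float) -> Physiology:
    """Pregnant physiology at gestational age ``ga`` (weeks) from a female base.

    Adds gestational weight gain, expands plasma/blood volume with
    haemodilution, grows the adipose and reproductive (utero-placental plus
    conceptus) compartments, raises renal flow with GFR and utero-placental
    flow with gestation; rest-of-body closes the volume balance.
    """
    if base.sex != "female":
        raise ValueError("pregnant physiology requires a female base")
    if not 0.0 <= ga <= 42.0:
        raise ValueError(f"gestational age {ga} outside [0, 42] weeks")
    if ga == 0.0:
        return base

    frac = ga / 40.0
    bw = base.body_weight + gestational_weight_gain(ga)
    hct = base.hematocrit * hematocrit_factor(ga)
    plasma = base.plasma_volume * plasma_volume_factor(ga)
    blood = plasma / (1.0 - hct)

    adipose_gain = 3.3 * frac ** 1.5
    reproductive_gain = 5.0 * frac ** 2.2  # uterus + placenta + conceptus

    new = {}
    for t in base.tissues:
        volume, flow = t.volume, t.blood_flow
        if t.name == "adipose":
            volume += adipose_gain
            flow *= volume / t.volume
        elif t.name == "reproductive":
            volume += reproductive_gain
            flow += 40.0 * frac ** 2  # utero-placental perfusion at term ~40 L/h
        elif t.name == "kidney":
            flow *= gfr_factor(ga)
        elif t.name == "skin":
            flow *= 1.0 + 0.30 * frac
        elif t.name == "rest_of_body":
            flow *= 1.0 + 0.20 * frac
        elif t.name == "arterial_blood":
            volume = blood * (base.tissue("arterial_blood").volume / base.blood_volume)
        elif t.name == "venous_blood":
            volume = blood * (base.tissue("venous_blood").volume / base.blood_volume)
        new[t.name] = replace(t, volume=volume, blood_flow=flow)

    # rest-of-body absorbs the remaining gain (interstitial fluid, mammary)
    other = sum(t.volume for n, t in new.items() if n != "rest_of_body")
    residual = bw / BODY_DENSITY - other
    rest = new["rest_of_body"]
    new["rest_of_body"] = replace(rest, volume=max(rest.volume, residual))

    co = sum(t.blood_flow for n, t in new.items()
             if n not in BLOOD_TISSUES and n != "lung")
    new["lung"] = replace(new["lung"], blood_flow=co)
    return Physiology(sex="female", body_weight=bw, gestational_age=ga,
                      tissues=tuple(new[t.name] for t in base.tissues),
                      cardiac_output=co,
                      glomerular_filtration_rate=base.glomerular_filtration_rate
                      * gfr_factor(ga),
                      hematocrit=hct, plasma_volume=plasma)


# ---------------------------------------------------------------------------
# delimited-text export / import

def export_physiology(phys: Physiology, path) -> None:
    df = pd.DataFrame({"tissue": [t.name for t in phys.tissues],
                       "volume_L": [t.volume for t in phys.tissues],
                       "flow_L_per_h": [t.blood_flow for t in phys.tissues]})
    df.to_csv(path, sep="\t", index=False)


def import_physiology(path, sex: str = "male", body_weight: float = 70.0,
                      **kwargs) -> Physiology:
    """Re-assemble a physiology from an exported table (compositions are
    re-attached from the bundled data)."""
    df = pd.read_csv(path, sep="\t")
    comp = tissue_composition_table()
    tissues = tuple(
        TissueCompartment(r.tissue, r.volume_L, r.flow_L_per_h,
                          comp.loc[r.tissue].to_dict() if r.tissue in comp.index else None)
        for r in df.itertuples())
    co = sum(t.blood_flow for t in tissues
             if t.name not in BLOOD_TISSUES and t.name != "lung")
    ref = REFERENCE[sex]
    defaults = dict(sex=sex, body_weight=body_weight, gestational_age=0.0,
                    cardiac_output=co, glomerular_filtration_rate=ref["gfr"],
                    hematocrit=ref["hematocrit"],
                    plasma_volume=sum(t.volume for t in tissues
                                      if t.name in BLOOD_TISSUES)
                    * (1 - ref["hematocrit"]))
    defaults.update(kwargs)
    return Physiology(tissues=tissues, **defaults)
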