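"""Drug, enzyme and interaction parameters.

Houses the physicochemical/biopharmaceutic profile of each compound, the
enzyme kinetic constants (Vmax, Km, fm, turnover) with their gestational
intrinsic-clearance trajectories, and the reversible-inhibition/induction
constants used by the DDI module.  Built-in profiles for lamotrigine
("LTG") and efavirenz ("EFV") ship as YAML data files mirroring the
source parameter tables field-for-field.

Canonical units: mass µg, volume mL, time h, concentration µg/mL;
Vmax is mg/s per mg enzyme and enzyme abundance is mg, so that
``vmax * abundance / km * 3600`` is an intrinsic clearance in L/h.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .units import VMAX_PER_KM_TO_L_PER_H

__all__ = [
    "DrugParameters",
    "EnzymeKinetics",
    "InteractionParameters",
    "GestationalClintTable",
    "DrugProfile",
    "solubility_at_ph",
    "scaled_intrinsic_clearance",
    "gestational_clint",
    "load_profile",
    "builtin_profile_names",
]

IONIZATION_CLASSES = ("monoprotic_base", "monoprotic_acid", "neutral")
DOSAGE_FORMS = ("IR_tablet", "IR_capsule")


class ParameterError(ValueError):
    """Invalid or missing parameter configuration."""


@dataclass(frozen=True)
class DrugParameters:
    """Physicochemical and biopharmaceutic profile of one compound.

    Solubilities are mg/mL, permeability cm/s, diffusion coefficient
    cm²/s, particle radius µm, particle density g/mL, dose volume mL,
    precipitation time s.
    """

    name: str
    molecular_weight: float
    log_p: float
    pka: float
    ionization_class: str
    intrinsic_solubility: float
    solubility_factor: float
    solubility_curve: tuple[tuple[float, float], ...]
    fassgf_solubility: float
    fassif_solubility: float
    blood_plasma_ratio: float
    fraction_unbound_plasma: float
    effective_permeability: float
    diffusion_coefficient: float
    mean_particle_radius: float
    particle_density: float
    dose_volume: float
    precipitation_time: float
    dosage_form: str

    def __post_init__(self) -> None:
        if self.ionization_class not in IONIZATION_CLASSES:
            raise ParameterError(f"unknown ionization_class {self.ionization_class!r}")
        if self.dosage_form not in DOSAGE_FORMS:
            raise ParameterError(f"unknown dosage_form {self.dosage_form!r}")
        if not 0.0 < self.fraction_unbound_plasma <= 1.0:
            raise ParameterError("fraction_unbound_plasma must be in (0, 1]")
        if self.blood_plasma_ratio <= 0:
            raise ParameterError("blood_plasma_ratio must be positive")
        if self.solubility_factor < 1.0:
            raise ParameterError("solubility_factor must be >= 1")
        for sol in (self.intrinsic_solubility, self.fassgf_solubility,
                    self.fassif_solubility):
            if sol <= 0:
                raise ParameterError("solubilities must be positive")
        if self.effective_permeability <= 0:
            raise ParameterError("effective_permeability must be positive")


@dataclass(frozen=True)
class EnzymeKinetics:
    """Michaelis-Menten kinetics of one elimination pathway.

    ``abundance`` (mg enzyme) is a calibration constant: for pathways with a
    reported non-pregnant Clint it is back-solved so that
    :func:`scaled_intrinsic_clearance` reproduces that value exactly.
    """

    enzyme: str
    location: str  # liver | gut | systemic
    vmax: float  # mg/s per mg enzyme
    km: float  # µg/mL
    fm: float  # % of total elimination
    turnover: float = 0.0  # 1/min degradation rate constant
    abundance: float | None = None  # mg enzyme

    def __post_init__(self) -> None:
        if self.vmax < 0:
            raise ParameterError("vmax must be >= 0")
        if self.km <= 0:
            raise ParameterError("km must be positive")
        if not 0.0 <= self.fm <= 100.0:
            raise ParameterError("fm must be a percentage in [0, 100]")
        if self.turnover < 0:
            raise ParameterError("turnover must be >= 0")
        if self.location not in ("liver", "gut", "systemic"):
            raise ParameterError(f"unknown enzyme location {self.location!r}")


@dataclass(frozen=True)
class InteractionParameters:
    """Perpetrator constants for one enzyme: Ki (µM) for reversible
    inhibition or EC50 (µM) and Emax for induction."""

    enzyme: str
    mechanism: str  # reversible_inhibition | induction
    constant: float  # µM
    emax: float = 0.0
    in_vitro_fu: float = 1.0
    in_vitro_protein_conc: float = 0.0  # mg/mL

    def __post_init__(self) -> None:
        if self.mechanism not in ("reversible_inhibition", "induction"):
            raise ParameterError(f"unknown mechanism {self.mechanism!r}")
        if self.constant <= 0:
            raise ParameterError("interaction constant must be positive")
        if self.mechanism == "induction" and self.emax < 0:
            raise ParameterError("emax must be >= 0 for induction")
        if not 0.0 < self.in_vitro_fu <= 1.0:
            raise ParameterError("in_vitro_fu must be in (0, 1]")


@dataclass(frozen=True)
class GestationalClintTable:
    """Intrinsic clearance (L/h) and fm (%) of one enzyme by gestational
    week; week 0 holds the non-pregnant values."""

    enzyme: str
    entries: tuple[tuple[float, float, float], ...]  # (week, clint, fm)

    def __post_init__(self) -> None:
        weeks = [e[0] for e in self.entries]
        if any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise ParameterError("gestational weeks must be strictly increasing")
        if any(e[1] <= 0 for e in self.entries):
            raise ParameterError("clint values must be positive")


@dataclass(frozen=True)
class DrugProfile:
    """A complete built-in drug: parameters, enzyme table, gestational
    trajectories, interaction constants and disposition calibration anchors."""

    drug: DrugParameters
    enzymes: tuple[EnzymeKinetics, ...]
    gestational_clint: dict[str, GestationalClintTable] = field(default_factory=dict)
    interactions: tuple[InteractionParameters, ...] = ()
    vss_target_l_per_kg: float | None = None
    total_clearance_l_per_h: float | None = None
    gut_fg_target: float | None = None

    @property
    def fm_total(self) -> float:
        """Sum of enzymatic fm (%); the remainder is the renal /
        non-enzymatic fraction."""
        total = sum(e.fm for e in self.enzymes)
        if total > 100.0 + 1e-9:
            raise ParameterError("sum of fm over enzymes exceeds 100%")
        return total


# ---------------------------------------------------------------------------
# operations


def solubility_at_ph(drug: DrugParameters, ph: float) -> float:
    """Aqueous solubility (mg/mL) at a given pH.

    Henderson-Hasselbalch scaling of the intrinsic solubility for the
    drug's ionization class, capped at ``intrinsic_solubility *
    solubility_factor``.  Measured curve points take precedence over the
    prediction when the requested pH coincides with one.
    """
    if not 0.0 <= ph <= 14.0:
        raise ValueError(f"pH {ph} outside [0, 14]")
    for curve_ph, curve_sol in drug.solubility_curve:
        if abs(ph - curve_ph) < 1e-6:
            return curve_sol
    if drug.ionization_class == "monoprotic_base":
        multiplier = 1.0 + 10.0 ** (drug.pka - ph)
    elif drug.ionization_class == "monoprotic_acid":
        multiplier = 1.0 + 10.0 ** (ph - drug.pka)
    else:
        multiplier = 1.0
    return min(drug.intrinsic_solubility * multiplier,
               drug.intrinsic_solubility * drug.solubility_factor)


def scaled_intrinsic_clearance(ek: EnzymeKinetics) -> float:
    """Linear-range intrinsic clearance, Vmax·abundance/Km, in L/h."""
    if ek.abundance is None:
        raise ParameterError(
            f"enzyme {ek.enzyme}: abundance not set; back-solve it from a "
            "reported Clint or run the clearance calibration first")
    return ek.vmax * ek.abundance / ek.km * VMAX_PER_KM_TO_L_PER_H


def abundance_from_clint(vmax: float, km: float, clint_l_per_h: float) -> float:
    """Back-solve the enzyme amount (mg) from a reported intrinsic clearance."""
    return clint_l_per_h * km / (vmax * VMAX_PER_KM_TO_L_PER_H)


def gestational_clint(table: GestationalClintTable, ga: float) -> float:
    """Intrinsic clearance (L/h) at gestational age ``ga`` (weeks).

    Printed values at tabulated weeks, linear interpolation in between;
    ga = 0 returns the non-pregnant value.
    """
    if not 0.0 <= ga <= 42.0:
        raise ValueError(f"gestational age {ga} outside [0, 42] weeks")
    weeks = np.array([e[0] for e in table.entries])
    clints = np.array([e[1] for e in table.entries])
    return float(np.interp(ga, weeks, clints))


def gestational_fm(table: GestationalClintTable, ga: float) -> float:
    """fm (%) at gestational age ``ga``, interpolated like the clearance."""
    if not 0.0 <= ga <= 42.0:
        raise ValueError(f"gestational age {ga} outside [0, 42] weeks")
    weeks = np.array([e[0] for e in table.entries])
    fms = np.array([e[2] for e in table.entries])
    return float(np.interp(ga, weeks, fms))


# ---------------------------------------------------------------------------
# built-in profiles

_BUILTINS = {"LTG": "ltg.yaml", "EFV": "efv.yaml"}


def builtin_profile_names() -> tuple[str, ...]:
    return tuple(_BUILTINS)


def _profile_from_dict(doc: dict) -> DrugProfile:
    d = dict(doc["drug"])
    d["solubility_curve"] = tuple((float(p), float(s)) for p, s in d["solubility_curve"])
    drug = DrugParameters(**d)
    enzymes = []
    for e in doc.get("enzymes", []):
        e = dict(e)
        clint = e.pop("clint", None)
        ek = EnzymeKinetics(**e)
        if clint is not None:
            ek = replace(ek, abundance=abundance_from_clint(ek.vmax, ek.km, clint))
        enzymes.append(ek)
    gtables = {}
    for enzyme, rows in (doc.get("gestational_clint") or {}).items():
        gtables[enzyme] = GestationalClintTable(
            enzyme=enzyme,
            entries=tuple((float(w), float(c), float(f)) for w, c, f in rows))
    interactions = tuple(InteractionParameters(**i) for i in doc.get("interactions", []))
    cal = doc.get("calibration", {})
    profile = DrugProfile(
        drug=drug,
        enzymes=tuple(enzymes),
        gestational_clint=gtables,
        interactions=interactions,
        vss_target_l_per_kg=cal.get("vss_target_l_per_kg"),
        total_clearance_l_per_h=cal.get("total_clearance_l_per_h"),
        gut_fg_target=cal.get("gut_fg_target"),
    )
    profile.fm_total  # validate the fm budget
    return profile


def load_profile(name_or_path: str) -> DrugProfile:
    """Load a built-in profile ("LTG", "EFV") or a YAML profile file."""
    key = name_or_path.upper()
    if key in _BUILTINS:
        ref = importlib.resources.files("pregpbpk.data") / _BUILTINS[key]
        text = ref.read_text()
    else:
        with open(name_or_path) as fh:
            text = fh.read()
    return _profile_from_dict(yaml.safe_load(text))
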