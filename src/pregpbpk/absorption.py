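"""Compartmental absorption and transit through the gastrointestinal tract.

A nine-segment fasted tract (stomach, duodenum, two jejunal, three ileal
segments, caecum, colon) with per-segment pH, fluid volume, transit rate
and absorptive surface.  Solid drug dissolves by a Johnson-type
particle-size-driven rate law, supersaturation precipitates first-order
with the drug's precipitation time, and dissolved drug permeates
passively (flux = Peff * area * concentration, colon surface reduced).
Biorelevant FaSSGF/FaSSIF solubilities override the
Henderson-Hasselbalch value in the stomach and upper intestine by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .parameters import DrugParameters, solubility_at_ph
from .physiology import Physiology
from .units import CM2_PER_S_TO_CM2_PER_H, CM_PER_S_TO_CM_PER_H, MG_TO_UG

__all__ = [
    "GICompartment",
    "AbsorptionAccounting",
    "MassBalanceError",
    "johnson_dissolution_rate",
    "build_gi_tract",
    "absorption_accounting",
]


class MassBalanceError(RuntimeError):
    """The simulation's mass-flux audit trail does not close."""

#: fasted-state defaults: name, fluid volume mL, pH, transit time h,
#: radius cm, absorption scale factor (0 disables uptake from the segment)
GI_DEFAULTS = (
    ("stomach", 250.0, 1.3, 0.50, 10.0, 0.0),
    ("duodenum", 42.0, 6.0, 0.26, 1.53, 1.0),
    ("jejunum1", 80.0, 6.2, 0.93, 1.45, 1.0),
    ("jejunum2", 60.0, 6.4, 0.74, 1.29, 1.0),
    ("ileum1", 45.0, 6.6, 0.58, 1.15, 1.0),
    ("ileum2", 35.0, 6.9, 0.42, 0.98, 1.0),
    ("ileum3", 25.0, 7.4, 0.29, 0.82, 1.0),
    ("caecum", 50.0, 6.4, 4.55, 3.50, 0.2),
    ("colon", 50.0, 6.8, 13.0, 2.50, 0.2),
)

UPPER_INTESTINE = ("duodenum", "jejunum1", "jejunum2")

#: hydrodynamic diffusion-layer cap, µm
DIFFUSION_LAYER_MAX_UM = 30.0


@dataclass(frozen=True)
class GICompartment:
    name: str
    volume: float       # mL of luminal fluid
    ph: float
    transit_rate: float  # 1/h
    radius: float       # cm, lumen radius setting the area-to-volume ratio
    absorption_scale: float
    solubility: float   # µg/mL local saturation solubility

    def __post_init__(self) -> None:
        if self.transit_rate <= 0:
            raise ValueError(f"{self.name}: transit_rate must be positive")

    @property
    def area(self) -> float:
        """Absorptive surface, cm² (cylindrical lumen times scale factor)."""
        return 2.0 * self.volume / self.radius * self.absorption_scale


@dataclass(frozen=True)
class AbsorptionAccounting:
    """Dose fractions: across the gut wall (Fa), reaching the portal vein
    (FDp) and systemically available (F), all in percent."""
    fa: float
    fdp: float
    f: float

    def __post_init__(self) -> None:
        eps = 1e-9
        if not -eps <= self.f <= self.fdp + eps <= self.fa + 2 * eps <= 100.0 + 3 * eps:
            raise ValueError(
                f"absorption ordering violated: F={self.f} FDp={self.fdp} Fa={self.fa}")


def johnson_dissolution_rate(drug: DrugParameters, undissolved: float,
                             dissolved_conc: float, solubility_local: float,
                             volume: float) -> float:
    """Dissolution rate (µg/h) of a polydisperse powder, Johnson form.

    rate = 3 D M (Cs - C) / (rho r h) with diffusion-layer thickness
    h = min(r, 30 µm).  A negative driving force returns 0; supersaturation
    is handled by the first-order precipitation pathway instead.
    """
    if drug.mean_particle_radius <= 0:
        raise ValueError("mean_particle_radius must be positive")
    if min(undissolved, dissolved_conc, solubility_local, volume) < 0:
        raise ValueError("masses and concentrations must be >= 0")
    driving = solubility_local - dissolved_conc
    if driving <= 0.0 or undissolved <= 0.0:
        return 0.0
    d = drug.diffusion_coefficient * CM2_PER_S_TO_CM2_PER_H  # cm²/h
    r = drug.mean_particle_radius * 1e-4  # cm
    h = min(drug.mean_particle_radius, DIFFUSION_LAYER_MAX_UM) * 1e-4
    rho = drug.particle_density * 1e6  # µg/mL
    return 3.0 * d * undissolved * driving / (rho * r * h)


def build_gi_tract(drug: DrugParameters, phys: Physiology,
                   stomach_transit_h: float = 0.5,
                   biorelevant: bool = True) -> list[GICompartment]:
    """Fasted-state tract with local solubilities resolved for the drug.

    The stomach transit time is exposed because gastric emptying dominates
    the absorption phase of rapidly permeating drugs (default 0.5 h);
    stomach fluid volume is set to the dose volume.
    """
    if stomach_transit_h <= 0:
        raise ValueError("stomach_transit_h must be positive")
    tract = []
    for name, volume, ph, transit, radius, asf in GI_DEFAULTS:
        if name == "stomach":
            volume = drug.dose_volume
            transit = stomach_transit_h
        if biorelevant and name == "stomach":
            sol = drug.fassgf_solubility
        elif biorelevant and name in UPPER_INTESTINE:
            sol = drug.fassif_solubility
        else:
            sol = solubility_at_ph(drug, ph)
        tract.append(GICompartment(name=name, volume=volume, ph=ph,
                                   transit_rate=1.0 / transit, radius=radius,
                                   absorption_scale=asf,
                                   solubility=sol * MG_TO_UG))
    return tract


def permeation_rate_constant(drug: DrugParameters, comp: GICompartment) -> float:
    """First-order uptake constant (1/h) from a segment's dissolved pool."""
    peff = drug.effective_permeability * CM_PER_S_TO_CM_PER_H  # cm/h
    return peff * comp.area / comp.volume


def absorption_accounting(sim, rel_tol: float = 1e-6) -> AbsorptionAccounting:
    """Fa / FDp / F from a completed simulation's cumulative mass fluxes.

    Fa is the cumulative flux across the apical gut wall, FDp subtracts
    gut-wall metabolism, and F applies the linear-limit hepatic extraction.
    The mass-flux audit trail must close to ``rel_tol`` of the dose.
    """
    error = sim.mass_balance_error()
    if error > rel_tol:
        raise MassBalanceError(
            f"mass balance off by {error:.2e} of the dose (tolerance {rel_tol:.0e})")
    if sim.dose_ug == 0:
        return AbsorptionAccounting(fa=0.0, fdp=0.0, f=0.0)
    led = sim.flux_ledger
    fa = led["absorbed"][-1] / sim.dose_ug * 100.0
    fdp = fa - led["gut_metabolized"][-1] / sim.dose_ug * 100.0
    f = fdp * (1.0 - sim.model.hepatic_extraction)
    return AbsorptionAccounting(fa=fa, fdp=fdp, f=f)
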