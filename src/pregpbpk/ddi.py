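"""Drug-drug interaction prediction: mechanistic-static ratios and dynamic
co-simulation.

The static model predicts the victim's AUC ratio from fm-weighted pathway
modifiers at a representative unbound perpetrator exposure,

    AUCR = 1 / ( sum_j fm_j * modifier_j + (1 - sum_j fm_j) ),
    modifier_j = (1 + Emax I/(EC50 + I)) / (1 + I/Ki),

with induction and inhibition terms defaulting to neutral when absent.

The dynamic mode simulates the perpetrator alone, then forces the
victim's system one way with the perpetrator's unbound liver
concentration: competitive Km inflation for reversible inhibition and
turnover-limited enzyme-level dynamics for induction,

    de/dt = kdeg (e0 (1 + Emax I/(EC50 + I)) - e).

No interaction constants exist for lamotrigine as a perpetrator, so an
efavirenz-as-victim run is unperturbed and its ratios are exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .absorption import absorption_accounting
from .engine import DoseRegimen, PBPKModel, simulate
from .models import build_model, build_physiology_for
from .parameters import InteractionParameters
from .pk_analysis import PKSummary, nca_summary
from .units import ug_per_ml_to_um

__all__ = [
    "DDIScenario",
    "DDIResult",
    "static_auc_ratio",
    "enzyme_dynamics_step",
    "simulate_ddi",
]

#: gestational-week -> victim dose (mg) preset used for the pregnancy series
TRIMESTER_DOSES_LTG = {10: 150.0, 20: 200.0, 30: 400.0, 40: 300.0}


@dataclass(frozen=True)
class DDIScenario:
    victim: tuple[str, float]  # (drug, dose mg)
    perpetrator: tuple[str, float]
    population: str = "adult_male"
    gestational_week: float = 0.0
    mode: str = "dynamic"  # dynamic | static
    duration: float = 24.0

    def __post_init__(self) -> None:
        if self.victim[1] < 0 or self.perpetrator[1] < 0:
            raise ValueError("doses must be >= 0")
        if self.mode not in ("dynamic", "static"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class DDIResult:
    scenario: DDIScenario
    baseline: dict[str, PKSummary]
    combined: dict[str, PKSummary]
    ratios: dict[str, dict[str, float]] = field(default_factory=dict)
    static_aucr: float | None = None
    perpetrator_exposure_um: float | None = None

    def to_dict(self) -> dict:
        def summarize(s: PKSummary) -> dict:
            return {k: getattr(s, k) for k in
                    ("cmax", "tmax", "auc_0_t", "auc_0_inf",
                     "fa_percent", "fdp_percent", "f_percent")}
        out = {"victim": self.scenario.victim[0],
               "perpetrator": self.scenario.perpetrator[0],
               "population": self.scenario.population,
               "gestational_week": self.scenario.gestational_week,
               "mode": self.scenario.mode,
               "ratios": self.ratios,
               "baseline": {d: summarize(s) for d, s in self.baseline.items()},
               "combined": {d: summarize(s) for d, s in self.combined.items()}}
        if self.static_aucr is not None:
            out["static_aucr"] = self.static_aucr
            out["perpetrator_exposure_um"] = self.perpetrator_exposure_um
        return out


def static_auc_ratio(victim_fm, perpetrator_exposure_u: float,
                     interactions) -> float:
    """Mechanistic-static victim AUC ratio (see module docstring).

    ``victim_fm``: (enzyme, fm %) pairs; ``perpetrator_exposure_u``: µM
    unbound exposure; missing induction/inhibition terms are neutral.
    """
    if perpetrator_exposure_u < 0:
        raise ValueError("exposure must be >= 0")
    fm_frac = [(enzyme, fm / 100.0) for enzyme, fm in victim_fm]
    if sum(f for _, f in fm_frac) > 1.0 + 1e-9:
        raise ValueError("sum of victim fm exceeds 100%")
    i = perpetrator_exposure_u
    denominator = 1.0 - sum(f for _, f in fm_frac)
    for enzyme, fm in fm_frac:
        induction = inhibition = 1.0
        for ip in interactions:
            if ip.enzyme != enzyme:
                continue
            if ip.mechanism == "induction":
                induction = 1.0 + ip.emax * i / (ip.constant + i)
            else:
                inhibition = 1.0 + i / ip.constant
        denominator += fm * induction / inhibition
    return 1.0 / denominator


def enzyme_dynamics_step(e: float, e0: float, kdeg: float, inducer_u: float,
                         emax: float, ec50: float) -> float:
    """d(e)/dt of the enzyme-turnover induction model, in kdeg's time unit."""
    if kdeg < 0:
        raise ValueError("kdeg must be >= 0")
    target = e0 * (1.0 + emax * inducer_u / (ec50 + inducer_u))
    return kdeg * (target - e)


def _unbound_liver_um(sim, model: PBPKModel):
    """Interpolant of the unbound liver concentration in µM."""
    cu = sim.unbound_liver_conc()
    cu_um = ug_per_ml_to_um(cu, model.drug.molecular_weight)
    t = sim.time_grid

    def interp(x):
        return float(np.interp(x, t, cu_um))
    return interp, float(np.mean(cu_um))


def _summary(sim, dose: float) -> PKSummary:
    from dataclasses import replace as _replace
    s = nca_summary(sim.time_grid, sim.plasma_conc, dose)
    acc = absorption_accounting(sim)
    return _replace(s, fa_percent=acc.fa, fdp_percent=acc.fdp, f_percent=acc.f,
                    cmax_liver=float(sim.liver_conc.max()))


def _ratios(base: PKSummary, comb: PKSummary) -> dict[str, float]:
    out = {}
    for key, attr in (("fa", "fa_percent"), ("fdp", "fdp_percent"),
                      ("f", "f_percent"), ("cmax", "cmax"), ("tmax", "tmax"),
                      ("auc_0_t", "auc_0_t"), ("auc_0_inf", "auc_0_inf")):
        b, c = getattr(base, attr), getattr(comb, attr)
        if b == c:  # includes the untouched-victim and zero-dose cases
            out[key] = 1.0
        elif b is not None and c is not None and b != 0:
            out[key] = c / b
        else:
            out[key] = float("nan")
    return out


def simulate_ddi(scenario: DDIScenario) -> DDIResult:
    """Baseline and combined runs for both drugs under a shared physiology.

    The combined victim run is forced by the perpetrator's unbound liver
    concentration through Km modifiers (Ki) and enzyme turnover (Emax/EC50).
    A perpetrator with zero dose or no interaction constants leaves the
    victim's system untouched, so those ratios are exactly 1 by
    construction.
    """
    (v_name, v_dose), (p_name, p_dose) = scenario.victim, scenario.perpetrator
    kw = dict(population=scenario.population,
              gestational_week=scenario.gestational_week)
    victim_model = build_model(v_name, **kw)
    perp_model = build_model(p_name, **kw)
    duration = scenario.duration

    baseline, combined, ratios = {}, {}, {}

    # victim under the perpetrator
    v_sim = simulate(victim_model, DoseRegimen(v_name, v_dose), duration)
    baseline[v_name] = _summary(v_sim, v_dose)
    p_sim = simulate(perp_model, DoseRegimen(p_name, p_dose), duration)
    baseline[p_name] = _summary(p_sim, p_dose)

    i_u, mean_exposure = _unbound_liver_um(p_sim, perp_model)
    perp_interactions = perp_model.interactions
    if scenario.mode == "static":
        victim_fm = [(e.enzyme, e.fm) for e in victim_model.liver_enzymes]
        aucr = static_auc_ratio(victim_fm, mean_exposure, perp_interactions)
        return DDIResult(scenario=scenario, baseline=baseline, combined={},
                         static_aucr=aucr, perpetrator_exposure_um=mean_exposure)

    coupled = (p_dose > 0 and any(
        ip.enzyme in {e.enzyme for e in victim_model.liver_enzymes}
        for ip in perp_interactions))
    if coupled:
        v_comb = simulate(victim_model, DoseRegimen(v_name, v_dose), duration,
                          perpetrator=(i_u, perp_interactions))
        combined[v_name] = _summary(v_comb, v_dose)
    else:
        combined[v_name] = baseline[v_name]  # neutral coupling: same system
    ratios[v_name] = _ratios(baseline[v_name], combined[v_name])

    # perpetrator as victim of the victim drug (emergent only: no constants
    # exist for the reverse direction unless its profile defines them)
    v_iu, _ = _unbound_liver_um(v_sim, victim_model)
    reverse = (v_dose > 0 and any(
        ip.enzyme in {e.enzyme for e in perp_model.liver_enzymes}
        for ip in victim_model.interactions))
    if reverse:
        p_comb = simulate(perp_model, DoseRegimen(p_name, p_dose), duration,
                          perpetrator=(v_iu, victim_model.interactions))
        combined[p_name] = _summary(p_comb, p_dose)
    else:
        combined[p_name] = baseline[p_name]
    ratios[p_name] = _ratios(baseline[p_name], combined[p_name])

    return DDIResult(scenario=scenario, baseline=baseline, combined=combined,
                     ratios=ratios, perpetrator_exposure_um=mean_exposure)


def gestational_ddi_series(victim: str = "LTG", perpetrator: str = "EFV",
                           perpetrator_dose: float = 600.0,
                           weeks=(10, 20, 30, 40), mode: str = "dynamic"):
    """The pregnancy DDI panel with the trimester dose preset."""
    results = []
    for ga in weeks:
        scenario = DDIScenario(victim=(victim, TRIMESTER_DOSES_LTG[ga]),
                               perpetrator=(perpetrator, perpetrator_dose),
                               population="pregnant", gestational_week=ga,
                               mode=mode)
        results.append(simulate_ddi(scenario))
    return results
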