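"""Scenario configuration and run orchestration.

One flat YAML document (unknown keys rejected) selects the drug(s),
population, doses and mode; :func:`run` executes the mode and writes
delimited-text profiles and JSON reports, each carrying a provenance
block (data-file hashes, package version, solver tolerances) so that
identical configurations reproduce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import importlib.metadata
import importlib.resources
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from . import engine
from .absorption import absorption_accounting
from .ddi import DDIScenario, simulate_ddi
from .engine import DoseRegimen, sensitivity_sweep, simulate
from .models import build_model
from .parameters import load_profile
from .partition import compute_kp_set
from .physiology import build_physiology
from .pk_analysis import (ObservedProfile, ValidationReport, fit_compartmental,
                          nca_summary)
from .synthetic import SyntheticSpec, builtin_fixtures, fixture_checksum, generate_profile

__all__ = ["ScenarioConfig", "parse_scenario", "run", "PRESETS"]

#: trimester dose presets (gestational week -> mg)
PRESETS = {"table2_ltg": {10: 150.0, 20: 200.0, 30: 400.0, 40: 300.0}}


class ScenarioError(ValueError):
    """Invalid scenario configuration."""


class ScenarioConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mode: Literal["simulate", "validate", "ddi", "fit", "kp", "synth", "sweep"]
    drugs: list[str] = ["LTG"]
    population: Literal["adult_male", "adult_female", "pregnant"] = "adult_male"
    gestational_week: float | None = None
    doses: list[float] | None = None
    preset: str | None = None
    duration: float = 24.0
    output_dir: str = "."
    seed: int = 0
    # mode-specific options
    sweep_parameter: str | None = None
    sweep_values: list[float] | None = None
    fit_profile: str | None = None
    fit_compartments: int = 1
    synth_spec: dict | None = None

    @model_validator(mode="after")
    def _check(self):
        if self.population == "pregnant" and not self.gestational_week:
            raise ValueError("pregnant population requires gestational_week")
        if self.mode == "ddi" and len(self.drugs) != 2:
            raise ValueError("ddi mode requires two drugs (victim, perpetrator)")
        if self.preset is not None:
            if self.preset not in PRESETS:
                raise ValueError(f"unknown preset {self.preset!r}")
            week = self.gestational_week
            table = PRESETS[self.preset]
            if week not in table:
                raise ValueError(f"preset {self.preset!r} has no dose for week {week}")
            self.doses = [table[week]] + (self.doses or [])[1:]
        if self.doses is None:
            self.doses = [200.0] * len(self.drugs)
        return self


def parse_scenario(text: str) -> ScenarioConfig:
    """Validated configuration from YAML text; unknown keys are rejected."""
    try:
        doc = yaml.safe_load(text) or {}
        return ScenarioConfig(**doc)
    except Exception as exc:
        raise ScenarioError(str(exc)) from exc


def provenance() -> dict:
    hashes = {}
    data = importlib.resources.files("pregpbpk.data")
    for ref in sorted(data.iterdir(), key=lambda r: r.name):
        if ref.name.endswith((".yaml", ".csv")):
            hashes[ref.name] = hashlib.sha256(ref.read_text().encode()).hexdigest()[:16]
    try:
        version = importlib.metadata.version("pregpbpk")
    except importlib.metadata.PackageNotFoundError:
        version = "unknown"
    return {"package_version": version, "data_hashes": hashes,
            "solver": {"rtol": engine.RTOL, "atol": engine.ATOL},
            "fixtures_sha256": fixture_checksum()}


def _write_json(path: Path, payload: dict) -> None:
    payload = dict(payload)
    payload["provenance"] = provenance()
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float) + "\n")


def _summary_dict(s, acc=None) -> dict:
    out = {"cmax_ug_per_ml": s.cmax, "tmax_h": s.tmax,
           "auc_0_t_ug_h_per_ml": s.auc_0_t, "auc_0_inf_ug_h_per_ml": s.auc_0_inf,
           "cl_over_f_l_per_h": s.cl_over_f}
    if acc is not None:
        out.update({"fa_percent": acc.fa, "fdp_percent": acc.fdp,
                    "f_percent": acc.f})
    return out


def run(config: ScenarioConfig) -> list[Path]:
    """Execute the scenario; returns the written artifact paths."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    ga = config.gestational_week or 0.0

    if config.mode == "simulate":
        for drug, dose in zip(config.drugs, config.doses):
            model = build_model(drug, config.population, gestational_week=ga)
            sim = simulate(model, DoseRegimen(drug, dose), config.duration)
            s = nca_summary(sim.time_grid, sim.plasma_conc, dose)
            acc = absorption_accounting(sim)
            profile_path = out / f"{drug.lower()}_profile.tsv"
            sim.export(profile_path)
            report = out / f"{drug.lower()}_summary.json"
            _write_json(report, {"drug": drug, "dose_mg": dose,
                                 "population": config.population,
                                 "gestational_week": ga,
                                 "summary": _summary_dict(s, acc)})
            written += [profile_path, report]

    elif config.mode == "validate":
        fixtures = builtin_fixtures()
        payload = {}
        for name, df in fixtures.items():
            report = ValidationReport()
            reported = []
            for row in df.itertuples():
                for qty in ("auc0t", "cmax", "tmax"):
                    pred = getattr(row, f"{qty}_pred")
                    obs = getattr(row, f"{qty}_obs")
                    if pred == pred and obs == obs:  # skip NaN cells
                        report.add(qty, pred, obs)
                        reported.append(getattr(row, f"{qty}_pe"))
            report.aggregate()
            # flag rows whose reported %PE does not recompute from its own
            # Pred/Obs pair (beyond reported-precision rounding)
            for r, pe_printed in zip(report.rows, reported):
                r["pe_printed"] = pe_printed
                r["pe_consistent"] = bool(abs(r["percent_pe"] - pe_printed) < 0.011)
            payload[name] = {"rows": report.rows, "aggregates": report.aggregates,
                             "accepted": report.accepted}
        path = out / "validation_report.json"
        _write_json(path, payload)
        written.append(path)

    elif config.mode == "ddi":
        victim, perp = config.drugs
        scenario = DDIScenario(victim=(victim, config.doses[0]),
                               perpetrator=(perp, config.doses[1]),
                               population=config.population, gestational_week=ga,
                               duration=config.duration)
        result = simulate_ddi(scenario)
        path = out / "ddi_report.json"
        _write_json(path, result.to_dict())
        written.append(path)

    elif config.mode == "fit":
        if not config.fit_profile:
            raise ScenarioError("fit mode requires fit_profile")
        profile = ObservedProfile.read(config.fit_profile)
        fit = fit_compartmental(profile, config.fit_compartments, seed=config.seed)
        path = out / "fit_report.json"
        _write_json(path, {"n_compartments": fit.n_compartments, "ka_per_h": fit.ka,
                           "cl_f_l_per_h": fit.cl_f, "vc_f_l": fit.vc_f,
                           "peripheral": list(fit.peripheral),
                           "objective": fit.objective, "aic": fit.aic})
        written.append(path)

    elif config.mode == "kp":
        for drug in config.drugs:
            profile = load_profile(drug)
            phys = build_physiology("male" if config.population == "adult_male"
                                    else "female")
            kps = compute_kp_set(profile.drug, phys)
            path = out / f"{drug.lower()}_kp.tsv"
            with open(path, "w") as fh:
                fh.write("tissue\tkp\n")
                for tissue, kp in kps.values.items():
                    fh.write(f"{tissue}\t{kp:.6g}\n")
            report = out / f"{drug.lower()}_kp.json"
            _write_json(report, {"drug": drug, "method": kps.method,
                                 "vss_l_per_kg": kps.vss_per_kg})
            written += [path, report]

    elif config.mode == "synth":
        spec = SyntheticSpec(seed=config.seed, **(config.synth_spec or
                                                  {"n_compartments": 1, "ka": 1.0,
                                                   "cl_f": 2.0, "vc_f": 80.0,
                                                   "dose": 200.0}))
        profile = generate_profile(spec)
        path = out / "synthetic_profile.tsv"
        profile.write(path)
        written.append(path)

    elif config.mode == "sweep":
        if not (config.sweep_parameter and config.sweep_values):
            raise ScenarioError("sweep mode requires sweep_parameter and sweep_values")
        drug, dose = config.drugs[0], config.doses[0]
        model = build_model(drug, config.population, gestational_week=ga)
        table = sensitivity_sweep(model, config.sweep_parameter,
                                  config.sweep_values,
                                  DoseRegimen(drug, dose), config.duration)
        path = out / "sweep.csv"
        table.to_csv(path, index=False)
        written.append(path)

    return written
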