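import dataclasses

import numpy as np
import pytest

from pregpbpk.absorption import absorption_accounting
from pregpbpk.engine import (DoseRegimen, michaelis_menten_rate,
                             sensitivity_sweep, simulate)
from pregpbpk.models import build_model
from pregpbpk.pk_analysis import nca_summary


class TestMichaelisMenten:
    def test_linear_limit_is_clint_times_cu(self):
        vmax, km, cu = 1000.0, 100.0, 0.01
        assert michaelis_menten_rate(vmax, km, cu) == pytest.approx(
            vmax / km * cu, rel=1e-3)

    def test_competitive_inhibition_halves_linear_rate(self):
        base = michaelis_menten_rate(1000.0, 100.0, 0.01)
        inhibited = michaelis_menten_rate(1000.0, 100.0, 0.01,
                                          inhibitor_u=2.0, ki=2.0)
        assert inhibited == pytest.approx(base / 2, rel=1e-3)

    def test_saturation(self):
        assert michaelis_menten_rate(1000.0, 1.0, 1e9) == pytest.approx(1000.0, rel=1e-6)


class TestSimulate:
    def test_zero_dose_zero_concentration(self, ltg_model):
        sim = simulate(ltg_model, DoseRegimen("LTG", 0.0), 6.0)
        assert np.all(sim.plasma_conc == 0.0)

    def test_ledger_conserved_throughout(self, ltg_sim):
        assert ltg_sim.mass_balance_error() <= 1e-6

    def test_plasma_nonnegative_and_starts_at_zero(self, ltg_sim):
        assert ltg_sim.plasma_conc[0] == 0.0
        assert np.all(ltg_sim.plasma_conc >= 0)

    def test_reporting_grid_resolution(self, ltg_sim):
        assert np.max(np.diff(ltg_sim.time_grid)) <= 0.1 + 1e-9

    def test_dose_linearity_for_ltg(self, ltg_model):
        # Km 147.95 µg/mL far above observed concentrations
        per_dose = {}
        for dose in (25.0, 100.0, 200.0):
            sim = simulate(ltg_model, DoseRegimen("LTG", dose), 24.0)
            s = nca_summary(sim.time_grid, sim.plasma_conc, dose)
            per_dose[dose] = s.auc_0_inf / dose
        values = np.array(list(per_dose.values()))
        assert values.max() / values.min() < 1.05

    def test_nca_auc_matches_direct_integral(self, ltg_sim):
        s = nca_summary(ltg_sim.time_grid, ltg_sim.plasma_conc, 200.0)
        direct = np.trapezoid(ltg_sim.plasma_conc, ltg_sim.time_grid)
        assert s.auc_0_t == pytest.approx(direct, rel=0.005)

    def test_single_compartment_reduction_matches_closed_form(self, ltg_model):
        # all Kp = 1 with a single linear systemic clearance on venous plasma
        # must reduce to AUC = F*Dose/CL (brute-force oracle equivalence)
        cl = 2.0  # L/h
        kps = dataclasses.replace(ltg_model.kps,
                                  values={k: 1.0 for k in ltg_model.kps.values},
                                  vss_per_kg=1.0)
        model = dataclasses.replace(ltg_model, kps=kps, enzymes=(),
                                    renal_clearance=0.0, systemic_clearance=cl)
        sim = simulate(model, DoseRegimen("LTG", 200.0), 360.0)
        s = nca_summary(sim.time_grid, sim.plasma_conc, 200.0)
        fa = sim.flux_ledger["absorbed"][-1] / sim.dose_ug
        expected = fa * 200.0 * 1000.0 / (cl * 1000.0)  # µg·h/mL
        assert s.auc_0_inf == pytest.approx(expected, rel=0.005)


class TestSensitivitySweep:
    def test_slower_gastric_emptying_delays_the_peak(self, ltg_model):
        table = sensitivity_sweep(ltg_model, "stomach_transit_h",
                                  [0.25, 0.5, 1.0], DoseRegimen("LTG", 200.0))
        tmax = table["tmax"].to_numpy()
        assert np.all(np.diff(tmax) > 0)

    def test_solubility_scalar_raises_fa_when_limited(self, ltg_model):
        # scale solubility down until dissolution limits absorption
        table = sensitivity_sweep(ltg_model, "solubility_scale",
                                  [0.001, 0.01], DoseRegimen("LTG", 200.0),
                                  duration=24.0)
        fa = table["fa"].to_numpy()
        assert fa[1] > fa[0]

    def test_shape(self, ltg_model):
        values = [0.4, 0.5, 0.6]
        table = sensitivity_sweep(ltg_model, "stomach_transit_h", values,
                                  DoseRegimen("LTG", 200.0), duration=6.0)
        assert len(table) == len(values)
        assert set(table.columns) >= {"value", "cmax", "tmax", "auc_0_t"}

    def test_unknown_parameter_rejected(self, ltg_model):
        with pytest.raises(ValueError):
            sensitivity_sweep(ltg_model, "no.such.parameter", [1.0],
                              DoseRegimen("LTG", 200.0))


class TestPopulationEffects:
    def test_female_ltg_exposure_slightly_above_male(self, ltg_sim):
        # smaller female body -> higher concentrations at the same dose
        model = build_model("LTG", "adult_female")
        sim = simulate(model, DoseRegimen("LTG", 200.0), 24.0)
        male = nca_summary(ltg_sim.time_grid, ltg_sim.plasma_conc, 200.0)
        female = nca_summary(sim.time_grid, sim.plasma_conc, 200.0)
        assert female.cmax > male.cmax

    def test_gestational_cmax_declines(self, ltg_pregnancy_sims):
        cmax = [sims.plasma_conc.max() for sims in ltg_pregnancy_sims.values()]
        assert all(b < a for a, b in zip(cmax, cmax[1:]))

    def test_efv_bioavailability_declines_with_gestation(self, efv_pregnancy_sims):
        f = [absorption_accounting(s).f for s in efv_pregnancy_sims.values()]
        assert all(b < a for a, b in zip(f, f[1:]))
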