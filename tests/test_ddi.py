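import numpy as np
import pytest

from pregpbpk.ddi import (DDIScenario, enzyme_dynamics_step, simulate_ddi,
                          static_auc_ratio)
from pregpbpk.engine import DoseRegimen, simulate
from pregpbpk.parameters import InteractionParameters, load_profile
from pregpbpk.pk_analysis import nca_summary

INHIBITION = InteractionParameters(enzyme="UGT1A4",
                                   mechanism="reversible_inhibition",
                                   constant=2.0)
INDUCTION = InteractionParameters(enzyme="UGT1A4", mechanism="induction",
                                  constant=1.0, emax=5.0)


class TestStaticRatio:
    def test_no_perpetrator_is_identity(self):
        assert static_auc_ratio([("UGT1A4", 79.9)], 0.0, [INHIBITION]) == 1.0

    def test_full_inhibition_at_ki_doubles_auc(self):
        assert static_auc_ratio([("UGT1A4", 100.0)], 2.0, [INHIBITION]) == pytest.approx(2.0)

    def test_ltg_pathway_set_closed_form(self):
        # hand evaluation: fm 79.9% inhibited by (1 + 1.0/2.0), fm 8.63%
        # untouched, 11.47% non-enzymatic remainder
        expected = 1.0 / (0.799 / 1.5 + 0.0863 + 1.0 - 0.799 - 0.0863)
        got = static_auc_ratio([("UGT1A4", 79.9), ("UGT1A3", 8.63)], 1.0,
                               [INHIBITION])
        assert got == pytest.approx(expected, rel=1e-12)
        assert got > 1.0

    def test_induction_only_depresses_auc(self):
        ratio = static_auc_ratio([("UGT1A4", 80.0)], 10.0, [INDUCTION])
        assert ratio < 1.0

    def test_fm_over_100_rejected(self):
        with pytest.raises(ValueError):
            static_auc_ratio([("A", 70.0), ("B", 40.0)], 1.0, [])


class TestEnzymeDynamics:
    def test_steady_state_without_inducer(self):
        assert enzyme_dynamics_step(e=1.0, e0=1.0, kdeg=0.0005,
                                    inducer_u=0.0, emax=5.76, ec50=0.82) == 0.0

    def test_analytic_induced_steady_state(self):
        i, emax, ec50 = 2.0, 5.76, 0.82
        target = 1.0 * (1.0 + emax * i / (ec50 + i))
        assert enzyme_dynamics_step(target, 1.0, 0.0005, i, emax, ec50) == pytest.approx(0.0)

    def test_turnover_time_constant(self):
        # kdeg 0.0005/min: relaxation time 1/kdeg = 2000 min ~ 33.3 h
        assert 1.0 / 0.0005 / 60.0 == pytest.approx(33.33, abs=0.01)
        step = enzyme_dynamics_step(0.0, 1.0, 0.0005, 0.0, 0.0, 1.0)
        assert step == pytest.approx(0.0005)  # per minute, toward baseline


class TestDynamicDDI:
    def test_null_perpetrator_all_ratios_exactly_one(self):
        result = simulate_ddi(DDIScenario(victim=("LTG", 200.0),
                                          perpetrator=("EFV", 0.0)))
        for ratios in result.ratios.values():
            for value in ratios.values():
                assert value == 1.0

    def test_inhibition_raises_victim_auc(self, adult_ddi):
        assert adult_ddi.ratios["LTG"]["auc_0_inf"] >= 1.0
        assert adult_ddi.ratios["LTG"]["auc_0_t"] >= 1.0

    def test_victim_cmax_barely_moves(self, adult_ddi):
        # clearance inhibition of a long-half-life drug leaves the single-dose
        # peak nearly unchanged
        assert adult_ddi.ratios["LTG"]["cmax"] == pytest.approx(1.0, abs=0.05)

    def test_reverse_direction_is_neutral_without_constants(self, adult_ddi):
        # no interaction constants exist for LTG as a perpetrator, so the
        # efavirenz ratios are exactly 1 (and in particular <= 1)
        for value in adult_ddi.ratios["EFV"].values():
            assert value == 1.0

    def test_induction_only_forcing_depresses_exposure(self, ltg_model):
        regimen = DoseRegimen("LTG", 200.0)
        base = simulate(ltg_model, regimen, 24.0)
        induced = simulate(ltg_model, regimen, 24.0,
                           perpetrator=(lambda t: 5.0, (INDUCTION,)))
        auc_base = nca_summary(base.time_grid, base.plasma_conc, 200.0).auc_0_inf
        auc_ind = nca_summary(induced.time_grid, induced.plasma_conc, 200.0).auc_0_inf
        assert auc_ind < auc_base

    def test_static_and_dynamic_agree_for_weak_interaction(self):
        scenario = DDIScenario(victim=("LTG", 200.0), perpetrator=("EFV", 10.0))
        dynamic = simulate_ddi(scenario)
        static = simulate_ddi(DDIScenario(victim=("LTG", 200.0),
                                          perpetrator=("EFV", 10.0),
                                          mode="static"))
        aucr_dyn = dynamic.ratios["LTG"]["auc_0_inf"]
        aucr_stat = static.static_aucr
        assert 0.9 < aucr_dyn < 1.1 and 0.9 < aucr_stat < 1.1
        assert aucr_dyn == pytest.approx(aucr_stat, rel=0.10)

    def test_report_serialization(self, adult_ddi):
        doc = adult_ddi.to_dict()
        assert doc["victim"] == "LTG" and doc["perpetrator"] == "EFV"
        assert "ratios" in doc and "baseline" in doc and "combined" in doc


def test_static_exposure_uses_unbound_liver_average(adult_ddi):
    # the perpetrator exposure metric is the mean unbound hepatic
    # concentration of the perpetrator's own simulation, in µM
    efv = load_profile("EFV")
    assert adult_ddi.perpetrator_exposure_um is not None
    assert 0.1 < adult_ddi.perpetrator_exposure_um < 20.0
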