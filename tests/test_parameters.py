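import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pregpbpk.parameters import (DrugParameters, DrugProfile, EnzymeKinetics,
                                 GestationalClintTable, ParameterError,
                                 gestational_clint, load_profile,
                                 scaled_intrinsic_clearance, solubility_at_ph)


@pytest.fixture(scope="module")
def ltg():
    return load_profile("LTG")


@pytest.fixture(scope="module")
def efv():
    return load_profile("EFV")


def make_drug(**overrides):
    base = dict(name="X", molecular_weight=250.0, log_p=1.0, pka=5.0,
                ionization_class="monoprotic_base", intrinsic_solubility=0.2,
                solubility_factor=20.0, solubility_curve=(),
                fassgf_solubility=1.0, fassif_solubility=0.5,
                blood_plasma_ratio=1.0, fraction_unbound_plasma=0.5,
                effective_permeability=5e-4, diffusion_coefficient=8e-6,
                mean_particle_radius=20.0, particle_density=1.2,
                dose_volume=250.0, precipitation_time=900.0,
                dosage_form="IR_tablet")
    base.update(overrides)
    return DrugParameters(**base)


class TestSolubility:
    def test_henderson_hasselbalch_base(self, ltg):
        # measured curve point: moderately ionized at pH 4.5
        assert solubility_at_ph(ltg.drug, 4.5) == pytest.approx(0.38, abs=0.005)
        # HH value without an override reproduces the same number
        bare = dataclasses.replace(ltg.drug, solubility_curve=())
        assert solubility_at_ph(bare, 4.5) == pytest.approx(0.38, abs=0.005)

    def test_cap_at_solubility_factor(self, ltg):
        # at pH 1.2 the uncapped HH value (~341 mg/mL) hits the 12.09x cap
        bare = dataclasses.replace(ltg.drug, solubility_curve=())
        assert solubility_at_ph(bare, 1.2) == pytest.approx(0.21 * 12.09, rel=1e-6)
        assert solubility_at_ph(ltg.drug, 1.2) == 2.54  # printed point

    def test_neutral_compound_is_ph_independent(self):
        drug = make_drug(ionization_class="neutral")
        assert all(solubility_at_ph(drug, ph) == drug.intrinsic_solubility
                   for ph in (1.0, 4.0, 7.4, 10.0))

    def test_ph_out_of_range(self, ltg):
        with pytest.raises(ValueError):
            solubility_at_ph(ltg.drug, -0.5)
        with pytest.raises(ValueError):
            solubility_at_ph(ltg.drug, 14.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(pka=st.floats(2.0, 11.0), logs0=st.floats(-3.0, 0.0),
           factor=st.floats(1.0, 1e4),
           ph=st.floats(0.0, 13.9), dph=st.floats(0.001, 3.0))
    def test_base_monotone_and_capped(self, pka, logs0, factor, ph, dph):
        s0 = 10.0 ** logs0
        drug = make_drug(pka=pka, intrinsic_solubility=s0, solubility_factor=factor)
        lo, hi = solubility_at_ph(drug, ph), solubility_at_ph(drug, min(ph + dph, 14))
        assert lo >= hi - 1e-12  # base: non-increasing with pH
        assert lo <= s0 * factor + 1e-12
        acid = make_drug(ionization_class="monoprotic_acid", pka=pka,
                         intrinsic_solubility=s0, solubility_factor=factor)
        assert solubility_at_ph(acid, ph) <= solubility_at_ph(acid, min(ph + dph, 14)) + 1e-12


class TestIntrinsicClearance:
    def test_reproduces_printed_clint(self, ltg):
        by_name = {e.enzyme: e for e in ltg.enzymes}
        assert scaled_intrinsic_clearance(by_name["UGT1A4"]) == pytest.approx(3.1564, rel=1e-9)
        assert scaled_intrinsic_clearance(by_name["UGT1A3"]) == pytest.approx(0.3411, rel=1e-9)

    def test_linearity_in_abundance_and_km_limit(self, ltg):
        e = ltg.enzymes[1]
        doubled = dataclasses.replace(e, abundance=e.abundance * 2)
        assert scaled_intrinsic_clearance(doubled) == pytest.approx(
            2 * scaled_intrinsic_clearance(e))
        stiff = dataclasses.replace(e, km=e.km * 1e9)
        assert scaled_intrinsic_clearance(stiff) < 1e-8

    def test_missing_abundance_is_configuration_error(self):
        e = EnzymeKinetics(enzyme="CYP0", location="liver", vmax=0.01, km=10.0,
                           fm=50.0)
        with pytest.raises(ParameterError, match="abundance"):
            scaled_intrinsic_clearance(e)


class TestGestationalClint:
    def test_printed_weeks_exact(self, ltg):
        table = ltg.gestational_clint["UGT1A4"]
        for week, clint, _fm in table.entries:
            assert gestational_clint(table, week) == clint
        assert gestational_clint(table, 40) == 2.41
        assert gestational_clint(table, 0) == 3.1564

    def test_linear_interpolation(self, ltg):
        table = ltg.gestational_clint["UGT1A4"]
        assert gestational_clint(table, 25) == pytest.approx((2.67 + 2.53) / 2, abs=1e-9)

    def test_missing_enzyme_is_lookup_error(self, ltg):
        with pytest.raises(KeyError):
            ltg.gestational_clint["CYP3A4"]

    def test_week_ordering_enforced(self):
        with pytest.raises(ParameterError):
            GestationalClintTable("U", entries=((10, 1.0, 10.0), (10, 0.9, 10.0)))


class TestProfiles:
    def test_fm_budget(self, ltg, efv):
        assert ltg.fm_total == pytest.approx(88.53)  # remainder is renal
        assert efv.fm_total <= 100.0

    def test_fm_over_100_rejected(self, ltg):
        bad = [dataclasses.replace(e, fm=60.0) for e in ltg.enzymes]
        with pytest.raises(ParameterError):
            DrugProfile(drug=ltg.drug, enzymes=tuple(bad)).fm_total

    def test_invariant_validation(self):
        with pytest.raises(ParameterError):
            make_drug(fraction_unbound_plasma=0.0)
        with pytest.raises(ParameterError):
            make_drug(solubility_factor=0.5)

    def test_efv_interaction_constants(self, efv):
        by = {(i.enzyme, i.mechanism) for i in efv.interactions}
        assert ("UGT1A4", "reversible_inhibition") in by
        assert ("CYP2B6", "induction") in by
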