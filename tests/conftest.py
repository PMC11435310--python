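import pytest

from pregpbpk.engine import DoseRegimen, simulate
from pregpbpk.models import build_model


@pytest.fixture(scope="session")
def ltg_model():
    return build_model("LTG", "adult_male")


@pytest.fixture(scope="session")
def ltg_sim(ltg_model):
    """200 mg single oral dose of lamotrigine in the standard adult."""
    return simulate(ltg_model, DoseRegimen("LTG", 200.0), 24.0)


@pytest.fixture(scope="session")
def efv_model():
    return build_model("EFV", "adult_male")


@pytest.fixture(scope="session")
def efv_sim(efv_model):
    """400 mg single oral dose of efavirenz in the standard adult."""
    return simulate(efv_model, DoseRegimen("EFV", 400.0), 24.0)


@pytest.fixture(scope="session")
def ltg_pregnancy_sims():
    """200 mg lamotrigine across gestational weeks 10-40."""
    out = {}
    for ga in (10, 20, 30, 40):
        model = build_model("LTG", "pregnant", gestational_week=ga)
        out[ga] = simulate(model, DoseRegimen("LTG", 200.0), 24.0)
    return out


@pytest.fixture(scope="session")
def efv_pregnancy_sims():
    """600 mg efavirenz across gestational weeks 10-40."""
    out = {}
    for ga in (10, 20, 30, 40):
        model = build_model("EFV", "pregnant", gestational_week=ga)
        out[ga] = simulate(model, DoseRegimen("EFV", 600.0), 24.0)
    return out


@pytest.fixture(scope="session")
def adult_ddi():
    from pregpbpk.ddi import DDIScenario, simulate_ddi
    return simulate_ddi(DDIScenario(victim=("LTG", 200.0),
                                    perpetrator=("EFV", 400.0)))
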