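import pytest

from avert.estimands import ArmObservation, TrialObservation
from avert.examples import covid_trial, discover_trial


@pytest.fixture
def discover() -> TrialObservation:
    return discover_trial()


@pytest.fixture
def covid() -> TrialObservation:
    return covid_trial()


@pytest.fixture
def discover_csv(tmp_path):
    p = tmp_path / "discover.csv"
    p.write_text(
        "arm,role,events,person_years\n"
        "TDF/FTC,control,11,4386\n"
        "TAF/FTC,experimental,6,4370\n"
    )
    return p


@pytest.fixture
def covid_csv(tmp_path):
    p = tmp_path / "covid.csv"
    p.write_text(
        "arm,role,events,person_years\n"
        "Experimental vaccine,experimental,80,10000\n"
        "BNT162b2,control,20,10000\n"
    )
    return p


def make_trial(x_c: int, t_c: float, x_e: int, t_e: float) -> TrialObservation:
    return TrialObservation(
        control=ArmObservation("C", x_c, t_c),
        experimental=ArmObservation("E", x_e, t_e),
    )
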