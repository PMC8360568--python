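import pytest

from aprepair.ap_model import (
    PacingProtocol,
    build_model,
    default_model_path,
    simulate,
)
from aprepair.biomarkers import compute_biomarkers
from aprepair.io import load_drug_library


@pytest.fixture(scope="session")
def library():
    return load_drug_library()


@pytest.fixture(scope="session")
def protocol():
    return PacingProtocol()


@pytest.fixture(scope="session")
def adult_wt():
    return build_model(default_model_path(), "adult-human", "WT")


@pytest.fixture(scope="session")
def adult_mutant():
    return build_model(default_model_path(), "adult-human", "N588K")


@pytest.fixture(scope="session")
def wt_trace(adult_wt, protocol):
    return simulate(adult_wt, protocol, record_currents=True)


@pytest.fixture(scope="session")
def mutant_trace(adult_mutant, protocol):
    return simulate(adult_mutant, protocol, record_currents=True)


@pytest.fixture(scope="session")
def wt_biomarkers(wt_trace):
    return compute_biomarkers(wt_trace)


@pytest.fixture(scope="session")
def mutant_biomarkers(mutant_trace):
    return compute_biomarkers(mutant_trace)
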