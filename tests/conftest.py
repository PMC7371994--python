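import pytest

from tsmr.harmonize import SelectionRules, select_instruments
from tsmr.summary_io import load_fixture

AIS_PROXY_MAP = {"rs6825454": "rs56010410"}


@pytest.fixture(scope="session")
def as_pair():
    return load_fixture("AS", "exposure"), load_fixture("AS", "outcome")


@pytest.fixture(scope="session")
def as_instruments(as_pair):
    kept, _ = select_instruments(*as_pair)
    return kept


@pytest.fixture(scope="session")
def as_steiger_instruments(as_pair):
    kept, _ = select_instruments(*as_pair, SelectionRules(drop_palindromic=True))
    return kept


@pytest.fixture(scope="session")
def ais_instruments():
    exposure = load_fixture("AIS", "exposure")
    outcome = load_fixture("AIS", "outcome")
    kept, _ = select_instruments(exposure, outcome, SelectionRules(proxy_map=AIS_PROXY_MAP))
    return kept


@pytest.fixture(scope="session")
def las_instruments():
    kept, _ = select_instruments(load_fixture("LAS", "exposure"), load_fixture("LAS", "outcome"))
    return kept


@pytest.fixture(scope="session")
def ces_instruments():
    kept, _ = select_instruments(load_fixture("CES", "exposure"), load_fixture("CES", "outcome"))
    return kept
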