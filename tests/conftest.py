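import json
import pathlib

import pytest

from biometeokit import MeteoRecord, SubjectProfile

DATA = pathlib.Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def default_subject() -> SubjectProfile:
    return SubjectProfile()


@pytest.fixture()
def neutral_record() -> MeteoRecord:
    return MeteoRecord(Ta=20.0, v=0.1, Tmrt=20.0, VP=12.5)


@pytest.fixture(scope="session")
def solar_oracle():
    with open(DATA / "solar_oracle.json") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def utci_grid():
    with open(DATA / "utci_grid.json") as fh:
        return json.load(fh)
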