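"""Shared fixtures.

The heavy session fixtures (the synthetic study population and the full
protocol run on it) are built once and shared by the recovery and
power tests; everything else builds tiny inputs inline.
"""

from __future__ import annotations

import numpy as np
import pytest

from wolfped.error_model import ErrorRates
from wolfped.genodata import AlleleFrequencyTable
from wolfped.protocol import ProtocolConfig, StudyData, run_protocol
from wolfped.synthetic_data import study_fixture

PROTOCOL_SEED = 11


@pytest.fixture(scope="session")
def fixture_truth():
    """The packaged synthetic study population (~80 wolves, 17 loci)."""
    demo, truth = study_fixture()
    return demo, truth


@pytest.fixture(scope="session")
def fixture_data(fixture_truth):
    _, truth = fixture_truth
    return StudyData.from_truth(truth)


@pytest.fixture(scope="session")
def protocol_result(fixture_data):
    """Full six-step protocol on the fixture at the desk-scale settings."""
    return run_protocol(fixture_data, ProtocolConfig.desk_scale(), seed=PROTOCOL_SEED)


@pytest.fixture()
def two_allele_freqs() -> AlleleFrequencyTable:
    return AlleleFrequencyTable({"loc": {"A": 0.5, "B": 0.5}})


@pytest.fixture()
def small_freqs() -> AlleleFrequencyTable:
    return AlleleFrequencyTable(
        {
            "l1": {"A": 0.4, "B": 0.6},
            "l2": {"A": 0.3, "B": 0.3, "C": 0.4},
            "l3": {"A": 0.1, "B": 0.2, "C": 0.3, "D": 0.4},
        }
    )


@pytest.fixture()
def zero_rates() -> ErrorRates:
    return ErrorRates(0.0, 0.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
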