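import pytest

from bsfplant import (
    TABLE_SCENARIOS,
    FattyAcidProfile,
    build_default_flowsheet,
    larvae_feed_stream,
    wet_basis_fractions,
)


@pytest.fixture(scope="session")
def control():
    return TABLE_SCENARIOS["control"]


@pytest.fixture(scope="session")
def kitchen_waste():
    return TABLE_SCENARIOS["kitchen_waste"]


@pytest.fixture(scope="session")
def default_profile():
    return FattyAcidProfile()


@pytest.fixture()
def control_feed(control, default_profile):
    return larvae_feed_stream(10_000.0, wet_basis_fractions(control), default_profile)


@pytest.fixture()
def default_plant():
    return build_default_flowsheet()
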