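import pytest

from farmbudget import case_study


@pytest.fixture(scope="session")
def study():
    farms, fluxes = case_study()
    return {f.farm_id: f for f in farms}, fluxes


@pytest.fixture(scope="session")
def farms(study):
    return study[0]


@pytest.fixture(scope="session")
def fluxes(study):
    return study[1]


def approx_printed(actual, printed, rel=0.005, printed_decimals=1):
    """True when `actual` agrees with a value printed at `printed_decimals`
    decimals: within `rel` relative, or within half a unit of the last
    printed digit (print-rounding of small terms)."""
    half_digit = 0.5 * 10 ** (-printed_decimals) + 1e-9
    return abs(actual - printed) <= max(rel * abs(printed), half_digit)
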