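import dataclasses

import pytest
from hypothesis import settings

from taxshift.market_data import CpiSeries
from taxshift.months import Month
from taxshift.synthetic_data import (
    ShiftPlan,
    default_paper_like_scenario,
    generate,
    synthetic_cpi,
    truth_assignments,
)
from taxshift.tax_engine import uk_timeline_2009_2015

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def timeline():
    return uk_timeline_2009_2015()


@pytest.fixture(scope="session")
def cpi():
    return synthetic_cpi()


@pytest.fixture(scope="session")
def default_market(cpi):
    """Default market scenario panel + ledger (seed 1), shared read-only."""
    scenario = default_paper_like_scenario(seed=1)
    records, ledger = generate(scenario, cpi=cpi)
    return scenario, records, ledger


@pytest.fixture(scope="session")
def null_market(cpi):
    """Default market with zero absorption and zero price noise: every
    tax change fully passed through, prices otherwise tracking CPI."""
    scenario = default_paper_like_scenario(seed=3)
    flat = ShiftPlan(absorb_pence=0.0)
    scenario = dataclasses.replace(
        scenario,
        price_noise_sd_gbp=0.0,
        segments=tuple(
            dataclasses.replace(s, shift=flat) for s in scenario.segments
        ),
    )
    records, ledger = generate(scenario, cpi=cpi)
    return scenario, records, ledger


@pytest.fixture(scope="session")
def truth_labels(default_market):
    _, _, ledger = default_market
    return truth_assignments(ledger)


@pytest.fixture
def tiny_cpi():
    """Two-month CPI with a 10% jump, base first."""
    base = Month(2010, 1)
    return CpiSeries(index={base: 100.0, Month(2010, 2): 110.0}, base_month=base)
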