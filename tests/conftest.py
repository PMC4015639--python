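import pytest

from cadcea import CostSchedule, TestPerformance, identity_link


@pytest.fixture
def perf():
    """Literature-default test performance (CMR 0.88/0.90, NDx 0.05)."""
    return TestPerformance()


@pytest.fixture
def costs():
    """Synthetic illustrative fee schedule used in the worked example."""
    return CostSchedule(
        f_cmr=1000.0,
        f_cxa_outpatient=2000.0,
        f_cxa_inpatient=3500.0,
        f_ffr=600.0,
        c_complication=10000.0,
        discount_rate=0.03,
        horizon_years=10,
    )


@pytest.fixture
def link():
    return identity_link()
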