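import pytest

import budfate as bf


@pytest.fixture(scope="session")
def corrected_records():
    return bf.load_table1("corrected")


@pytest.fixture(scope="session")
def raw_records():
    return bf.load_table1("raw")


@pytest.fixture(scope="session")
def reference_params():
    return bf.REFERENCE_PARAMS


@pytest.fixture(scope="session")
def selected_fit(corrected_records):
    """Stepwise-selected fit on the corrected study data (shared, read-only)."""
    return bf.stepwise_backward_aic(corrected_records).fit
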