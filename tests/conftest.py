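import pytest

from qamskit import io


@pytest.fixture(scope="session")
def calib():
    return io.load_reference_calibration()


@pytest.fixture(scope="session")
def peak_panel():
    return io.load_reference_peak_areas()


@pytest.fixture(scope="session")
def content_tables():
    return io.load_reference_contents()


@pytest.fixture(scope="session")
def printed_totals():
    return io.load_reference_totals()
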