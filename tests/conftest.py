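import numpy as np
import pytest

from alpc.records import ECGRecord, Lead
from alpc.synthetic import make_fixture_suite


@pytest.fixture(scope="session")
def fixture_suite():
    """The standard 9-record synthetic regression corpus (3 presets x 3 variants)."""
    return make_fixture_suite(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_record(samples, bits=12, fs=250.0, signed=True, name="test"):
    """Small helper: wrap an integer array as a single-lead record."""
    return ECGRecord(
        name=name,
        fs=fs,
        resolution_bits=bits,
        leads=[Lead(name="I", samples=np.asarray(samples, dtype=np.int64))],
        signed=signed,
    )
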