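import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from helpers import toy_partition  # noqa: E402


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def partition_e2():
    return toy_partition(2)


@pytest.fixture(scope="session")
def recording_60s():
    """One synthetic 60 s trial at 128 Hz (no couplings)."""
    from crossgc.synthetic import SynthConfig, generate_recording

    return generate_recording(SynthConfig(seed=99), "HAHV")
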