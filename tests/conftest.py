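import numpy as np
import pytest

from fearpeth import (
    BehaviorModelParams,
    ClassifierParams,
    build_timeline,
    default_protocol,
    simulate_behavior,
)


@pytest.fixture(scope="session")
def retrieval_timeline():
    """One fixed retrieval session (6 unpaired CS)."""
    return build_timeline(default_protocol("RETRIEVAL"), seed=12345)


@pytest.fixture(scope="session")
def prf_timeline():
    return build_timeline(default_protocol("PRF"), seed=12345)


@pytest.fixture(scope="session")
def frf_timeline():
    return build_timeline(default_protocol("FRF"), seed=12345)


@pytest.fixture(scope="session")
def behavior_trace(retrieval_timeline):
    return simulate_behavior(retrieval_timeline, BehaviorModelParams(), seed=99)


@pytest.fixture
def cs_params():
    return ClassifierParams()


@pytest.fixture
def freeze_params():
    return ClassifierParams(baseline_offset=1.0)


def unit_seeds(master: int, n: int) -> list[int]:
    """Deterministic per-unit seeds below 2**31.

    Uses ``SeedSequence([master, i])`` keying; truncating spawned children
    to a single word gives visibly correlated streams.
    """
    return [
        int(np.random.SeedSequence([master, i]).generate_state(1)[0] % 2**31)
        for i in range(n)
    ]
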