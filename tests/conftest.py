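import numpy as np
import pytest

from mrmod.pwm import PWM


def sharp_pwm(id: str, consensus: str, count: float = 194.0, other: float = 2.0) -> PWM:
    """A high-information motif concentrated on the given consensus."""
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = np.full((len(consensus), 4), other)
    for j, b in enumerate(consensus):
        counts[j, base_index[b]] = count
    return PWM(id, counts)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def high_ic_pwm():
    return sharp_pwm("hi", "ACGTAGCTAC")


@pytest.fixture
def a_pwm():
    """1-column A-biased matrix with exact log-odds ln 3 for A."""
    return PWM("a1", [[3, 1, 0, 0]], pseudocount=0.0)
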