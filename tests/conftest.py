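import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lncsift import synth
from lncsift.seqio import Transcript

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), size=length)])


@pytest.fixture(scope="session")
def small_dataset():
    """200+200 synthetic transcripts, shared across model-level tests."""
    p = synth.SynthParams(n_pos=200, n_neg=200, length_range=(200, 1200), seed=42)
    return synth.simulate_dataset(p)


@pytest.fixture
def transcript():
    def make(seq: str, tid: str = "t", label: str | None = None) -> Transcript:
        return Transcript(id=tid, seq=seq, label=label)

    return make
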