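import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

_MUT = {"A": "C", "C": "G", "G": "T", "T": "A"}


def mutate_at(seq: str, positions) -> str:
    out = list(seq)
    for pos in positions:
        out[pos] = _MUT[out[pos]]
    return "".join(out)


@pytest.fixture
def rng():
    return np.random.default_rng(20130626)


@pytest.fixture
def random_seq(rng):
    def make(length: int) -> str:
        return "".join(rng.choice(list("ACGT"), length))
    return make


@pytest.fixture
def table1_rows():
    from uceflow.enrichment import table_rows
    from uceflow.io import load_table1_fixture
    return table_rows(load_table1_fixture())
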