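import numpy as np
import pytest

from upstreamx.io_formats import PromoterRecord, Pwm
from upstreamx.synthetic_data import make_sharp_pwm


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def sharp_pwm(rng):
    """Near-deterministic 10-bp motif (dominant base weight 97:1)."""
    return make_sharp_pwm("SHARP", 10, rng)


@pytest.fixture
def consensus_pwm():
    """Fully deterministic 6-bp motif ACGTAC with pseudocount 0."""
    counts = np.zeros((6, 4))
    for i, base in enumerate("ACGTAC"):
        counts[i, "ACGT".index(base)] = 10.0
    return Pwm("CONS", counts, pseudocount=0.0)


@pytest.fixture
def random_pwm_library(rng):
    return [make_sharp_pwm(f"M{k:02d}", int(rng.integers(8, 13)), rng)
            for k in range(6)]


def make_promoter(gene_id: str, seq: str) -> PromoterRecord:
    return PromoterRecord(gene_id, seq, tss_offset=max(len(seq) - 100, 0))
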