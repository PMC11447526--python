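import numpy as np
import pytest

from cenbarcode.synthetic_data import (
    PARTIAL_FRACTIONS,
    SimulationConfig,
    build_hor_array,
    default_family_consensus,
)

BASES = "ACGT"


@pytest.fixture(scope="session")
def consensus():
    """Synthetic family consensus monomers (92 / 91 / 413 bp)."""
    return default_family_consensus()


@pytest.fixture(scope="session")
def cons4(consensus):
    return consensus["CentGm-4"]


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each base with probability `rate` (never to itself)."""
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = BASES[(BASES.index(out[i]) + 1 + int(rng.integers(3))) % 4]
    return "".join(out)


@pytest.fixture(scope="session")
def noisy_array(cons4):
    """A 100-copy substitution-only CentGm-4-type array with one truncated
    copy at each of the three canonical fractions, plus its ground truth."""
    config = SimulationConfig(
        n_copies=100,
        sub_rate=0.03,
        seed=45,
        truncation_fractions=PARTIAL_FRACTIONS,
        truncation_count=3,
    )
    return build_hor_array(config, consensus=cons4)
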