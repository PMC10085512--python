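import numpy as np
import pytest

from pacseq import SimSpec, SourcePool, gen_references


@pytest.fixture(scope="session")
def adapter() -> str:
    return "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"


@pytest.fixture()
def two_pool_spec(adapter) -> SimSpec:
    """Small two-source experiment: a host pool and a contaminant pool."""
    host = SourcePool("host", gen_references(11, 6, 300))
    microbe = SourcePool("microbe", gen_references(22, 6, 300))
    return SimSpec(
        pools=[host, microbe],
        per_sample_mixture={
            "s1": {"host": 0.8, "microbe": 0.2},
            "s2": {"host": 0.5, "microbe": 0.5},
            "s3": {"host": 0.2, "microbe": 0.8},
        },
        n_reads_per_sample=400,
        adapter=adapter,
        seed=7,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
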