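import numpy as np
import pytest

from asmram.synth import synth_abundance_fixture, synth_training_table


def random_reads(rng: np.random.Generator, n_reads: int, max_len: int = 200) -> list[str]:
    """Random A/C/G/T reads with occasional N bases and variable lengths."""
    alphabet = np.array(list("ACGTN"))
    probs = np.array([0.24, 0.24, 0.24, 0.24, 0.04])
    reads = []
    for _ in range(n_reads):
        length = int(rng.integers(5, max_len + 1))
        reads.append("".join(rng.choice(alphabet, size=length, p=probs)))
    return reads


@pytest.fixture(scope="session")
def training_table_300():
    table, truth = synth_training_table(n_datasets=300, noise_sd=2.0, seed=11)
    return table, truth


@pytest.fixture(scope="session")
def abundance_fixture():
    regions = {f"region_{r}": [f"country_{r}{c}" for c in range(5)] for r in range(3)}
    table, metadata, truth = synth_abundance_fixture(
        regions, samples_per_country=10, seed=7
    )
    return table, metadata, truth
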