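import numpy as np
import pytest

from dsite import (
    DinucleotidePropertyTable,
    EncoderContext,
    SyntheticSpec,
    generate_benchmark,
    load_property_table,
    validate_window,
)

SEED = 7


@pytest.fixture(scope="session")
def table() -> DinucleotidePropertyTable:
    return load_property_table()


@pytest.fixture(scope="session")
def ctx(table) -> EncoderContext:
    return EncoderContext(table=table)


@pytest.fixture(scope="session")
def valid_window():
    return validate_window("w1", "A" * 20 + "U" + "A" * 20)


@pytest.fixture(scope="session")
def random_windows(table):
    """200 random valid windows (uniform background, center U)."""
    rng = np.random.default_rng(SEED)
    bases = np.array(list("ACGU"))
    windows = []
    for k in range(200):
        seq = "".join(bases[rng.integers(0, 4, size=41)])
        seq = seq[:20] + "U" + seq[21:]
        windows.append(validate_window(f"r{k}", seq))
    return windows


@pytest.fixture(scope="session")
def separable_dataset():
    """Small strongly separable benchmark (30+30) for classifier tests."""
    return generate_benchmark(
        SyntheticSpec(n_pos=30, n_neg=30, separability=1.0, seed=SEED)
    )
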