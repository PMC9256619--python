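import numpy as np
import pandas as pd
import pytest

from droughtnet import synth


@pytest.fixture(scope="session")
def small_design():
    """One-compartment version of the study design (6 plots, weeks 1-17)."""
    return synth.DesignSpec(compartments=("rhizosphere",))


@pytest.fixture(scope="session")
def small_dataset(small_design):
    """Default planted effects, 40 bacteria + 20 fungi, fixed seed."""
    return synth.generate_counts(small_design, synth.EffectSpec(), 40, 20, seed=11)


@pytest.fixture(scope="session")
def null_dataset(small_design):
    """All effects zeroed: treatments exchangeable."""
    return synth.generate_counts(small_design, synth.EffectSpec.null(), 40, 20, seed=11)


@pytest.fixture
def tiny_counts():
    """Hand-sized count table: 4 samples x 3 taxa."""
    return pd.DataFrame(
        [[1, 2, 3], [3, 2, 1], [0, 0, 6], [2, 2, 2]],
        index=["s1", "s2", "s3", "s4"],
        columns=["tA", "tB", "tC"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
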