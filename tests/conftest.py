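import numpy as np
import pytest

from methylcapso import DnaRecord, SyntheticConfig, generate_synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def random_sequences(rng):
    """100 random ACGT sequences of length 2..64."""
    bases = np.array(list("ACGT"))
    return [
        "".join(rng.choice(bases, size=rng.integers(2, 65))) for _ in range(100)
    ]


@pytest.fixture
def small_dataset():
    """A quick separable motif-planted dataset (mutation-free motif)."""
    return generate_synthetic(
        SyntheticConfig(n_pos=60, n_neg=60, length=21, motif="GAGGTA",
                        mutation_rate=0.0, seed=5)
    )


@pytest.fixture
def labeled_records():
    return [
        DnaRecord("pos_0", "ACGTACGTAC", 1),
        DnaRecord("neg_0", "TTTTGGGGCC", 0),
        DnaRecord("pos_1", "GGGGACGTTT", 1, species="H.sapiens", mod_type="6mA"),
    ]
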