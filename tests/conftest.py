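import numpy as np
import pytest

from vosshog.encoding import ALPHABET, NucleotideSequence
from vosshog.synthetic_data import CorpusConfig, generate_corpus

#: Short gene stand-ins so unit tests stay fast; descriptor geometry and
#: mutation semantics do not depend on the real lengths.
SMALL_GENES = {"EGFR": 120, "KRAS": 60, "TP53": 90}


def random_sequence(rng: np.random.Generator, length: int,
                    id: str = "rand") -> NucleotideSequence:
    return NucleotideSequence(
        id, "".join(ALPHABET[i] for i in rng.integers(0, 4, size=length)))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_corpus():
    """Fast six-class corpus over short genes (deterministic)."""
    cfg = CorpusConfig(
        gene_lengths=dict(SMALL_GENES),
        class_counts={"normal": 6, "EGFR_deletion": 10,
                      "EGFR_substitution": 10, "KRAS_substitution": 10,
                      "TP53_deletion": 10, "TP53_substitution": 10},
        deletion_length_range=(3, 12),
        seed=7,
    )
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def toy_two_class():
    """Linearly separable two-cluster dataset (40 points, 81 features)."""
    rng = np.random.default_rng(99)
    centers = np.zeros((2, 81))
    centers[0, 0], centers[1, 0] = -3.0, 3.0
    X = np.vstack([rng.normal(centers[k], 0.3, size=(20, 81)) for k in (0, 1)])
    y = np.repeat([0, 1], 20)
    return X, y
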