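import numpy as np
import pytest

from foldmap.sequence import RnaSequence, make_sequence


def random_sequence(rng: np.random.Generator, L: int, id: str = "rnd") -> RnaSequence:
    return make_sequence("".join(rng.choice(list("ACGU"), L)), id=id)


def random_symmetric_scores(rng: np.random.Generator, L: int, scale: float = 1.0):
    S = rng.normal(0.0, scale, (L, L))
    return 0.5 * (S + S.T)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_corpus():
    """A small deterministic synthetic corpus shared across tests."""
    from foldmap.fixtures import FixtureConfig, generate_corpus

    return generate_corpus(
        FixtureConfig(n_sequences=20, length_min=30, length_max=60,
                      pseudoknot_probability=0.4, seed=42)
    )
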