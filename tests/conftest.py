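import numpy as np
import pytest

import mirnacle as m


@pytest.fixture(scope="session")
def energy():
    return m.StackingEnergyModel()


@pytest.fixture(scope="session")
def small_corpus():
    """60 synthetic hairpin positives + 60 negatives (shared across tests)."""
    return m.training_sequences(60, 60, seed=11)


@pytest.fixture(scope="session")
def small_cascade(small_corpus):
    pos, neg = small_corpus
    return m.train_cascade(pos, neg, seed=11, n_trees=50)


@pytest.fixture(scope="session")
def small_genome():
    """~2.5-kb synthetic genome with 2 implanted strong hairpins."""
    specs = [m.HairpinSpec(stem=30, loop=8, seed=k) for k in range(2)]
    return m.implant(2500, specs, seed=5)


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), length))
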