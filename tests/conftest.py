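import numpy as np
import pytest

import winelattice as wl
from winelattice.datasets import animals_context, bruce_carlo_context
from winelattice.synthetic import default_spec, generate


@pytest.fixture(scope="session")
def lexicon():
    return wl.default_lexicon()


@pytest.fixture(scope="session")
def animals():
    return animals_context()


@pytest.fixture(scope="session")
def bruce_carlo():
    return bruce_carlo_context()


@pytest.fixture(scope="session")
def default_corpus(lexicon):
    """One default synthetic corpus (seed 1) with its ground truth,
    standardised once for the whole session."""
    reviews, truth = generate(default_spec(seed=1), lexicon)
    std = wl.standardize_corpus(reviews, lexicon)
    return reviews, std, truth


def random_context(rng, n_obj, n_attr, density):
    inc = rng.random((n_obj, n_attr)) < density
    return wl.FormalContext(
        [f"g{i}" for i in range(n_obj)],
        [f"m{j}" for j in range(n_attr)],
        inc,
    )
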