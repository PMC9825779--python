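import numpy as np
import pytest

from contribdiv import FixtureSpec, generate_fixture, generate_toy_worked_example


@pytest.fixture
def toy():
    return generate_toy_worked_example()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_dataset():
    """10 taxa x 6 samples x 8 functions with a covering tree."""
    return generate_fixture(FixtureSpec(n_taxa=10, n_samples=6, n_functions=8, seed=7))


def random_abundance_vectors(rng, n=100, max_len=12):
    """Mixed continuous vectors, some sparse, some degenerate."""
    out = []
    for _ in range(n):
        k = int(rng.integers(1, max_len + 1))
        v = rng.lognormal(0, 1, size=k)
        v[rng.random(k) < 0.3] = 0.0
        out.append(v)
    out.append(np.zeros(5))
    out.append(np.array([3.0]))
    return out


def random_count_vectors(rng, n=100, max_len=12):
    out = []
    for _ in range(n):
        k = int(rng.integers(1, max_len + 1))
        v = rng.integers(0, 50, size=k).astype(float)
        out.append(v)
    out.append(np.zeros(4))
    out.append(np.array([1.0, 2.0, 3.0]))
    return out
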