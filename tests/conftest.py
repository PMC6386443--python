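import numpy as np
import pytest

from glcminv import CooccurrenceCounts, normalize_density, normalize_pmf, standard_offsets


def random_counts(rng, n_levels, max_count=30):
    """A random non-degenerate co-occurrence count matrix."""
    x = rng.integers(0, max_count, size=(n_levels, n_levels))
    # guarantee at least two occupied gray-levels
    x[0, 1] += 1
    x[1, 0] += 1
    return CooccurrenceCounts(
        matrix=x, n_levels=n_levels, offsets=standard_offsets(2), symmetric=False
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def uniform_glcms():
    """Uniform-count GLCMs at N=4, both variants."""
    counts = CooccurrenceCounts(
        matrix=np.ones((4, 4), dtype=int),
        n_levels=4,
        offsets=standard_offsets(2, semi_invariant=True),
        symmetric=True,
    )
    return normalize_pmf(counts), normalize_density(counts)
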