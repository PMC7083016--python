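import numpy as np
import pytest

from npem.entropy import MICache, Variable


@pytest.fixture
def rng():
    return np.random.default_rng(20240317)


def make_noise_cache(seed: int, n_candidates: int = 20, n: int = 40, kind="categorical"):
    """A cache of mutually independent candidates plus an independent target."""
    rng = np.random.default_rng(seed)
    cache = MICache()
    if kind == "categorical":
        ids = [
            cache.add(Variable(rng.integers(0, 2, n), "categorical"))
            for _ in range(n_candidates)
        ]
        target = cache.add(Variable(rng.integers(0, 2, n), "categorical"))
    else:
        ids = [cache.add(Variable(rng.normal(size=n))) for _ in range(n_candidates)]
        target = cache.add(Variable(rng.normal(size=n)))
    return cache, ids, target
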