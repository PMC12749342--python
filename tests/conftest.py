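"""Shared fixtures: cached synthetic pairs so expensive renders run once."""

import numpy as np
import pytest

import clxmreg as cx


@pytest.fixture(scope="session")
def pair_cache():
    """Memoised default correlative pairs keyed by (seed, noise, with_warp)."""
    cache = {}

    def get(seed, noise=True, with_warp=True):
        key = (seed, noise, with_warp)
        if key not in cache:
            cache[key] = cx.default_correlative_pair(seed, noise=noise,
                                                     with_warp=with_warp)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def registered_seed1(pair_cache):
    """Full registration of the default seed-1 pair (with warp + noise)."""
    fm, sxt, scene, gt = pair_cache(1)
    res = cx.register_pair(sxt, fm, make_overlay=False)
    return fm, sxt, scene, gt, res


@pytest.fixture
def rng():
    return np.random.default_rng(42)
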