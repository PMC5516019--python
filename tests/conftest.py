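import math

import numpy as np
import pytest

from msbind import (
    LigandReservoir,
    PerSiteConstants,
    compute_all_constants,
    load_kv12_affinities,
    load_kv12_printed,
    make_context,
)


@pytest.fixture(scope="session")
def ctx():
    return make_context(298.15)


@pytest.fixture(scope="session")
def reservoir():
    return LigandReservoir(excess_chemical_potential=-0.1, concentration=0.0)


@pytest.fixture(scope="session")
def kv12_sites():
    return load_kv12_affinities()


@pytest.fixture(scope="session")
def kv12_printed():
    return load_kv12_printed()


@pytest.fixture(scope="session")
def kv12_constants(kv12_sites, reservoir, ctx):
    return compute_all_constants(kv12_sites, reservoir, ctx)


def make_constants(site_id: str, Ks, region: str = "toy") -> PerSiteConstants:
    """PerSiteConstants straight from K values (mM⁻ⁿ), K_0 implied."""
    log_K = (0.0,) + tuple(math.log(k) for k in Ks)
    return PerSiteConstants(
        site_id=site_id,
        region=region,
        log_K=log_K,
        log_K_bounds=tuple((lk, lk) for lk in log_K),
    )


@pytest.fixture
def toy3():
    """Three sites with hand-picked constants; 2·3·2 = 12 states."""
    return [
        make_constants("a", [2.0]),
        make_constants("b", [3.0, 1.5]),
        make_constants("c", [0.25]),
    ]


def brute_force_probabilities(per_site, rho_mM):
    """Independent oracle: enumerate states with plain-float arithmetic."""
    import itertools

    ranges = [range(p.max_occupancy + 1) for p in per_site]
    states = list(itertools.product(*ranges))
    weights = []
    for st in states:
        w = 1.0
        for p, n in zip(per_site, st):
            w *= rho_mM**n * math.exp(p.log_K[n]) if n else 1.0
        weights.append(w)
    Z = sum(weights)
    return {st: w / Z for st, w in zip(states, weights)}
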