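import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_phantom():
    from itrait.phantoms import PhantomSpec, make_image_phantoms

    return make_image_phantoms(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def small_genotypes():
    from itrait.simulate import simulate_genotypes

    return simulate_genotypes(150, 300, maf_min=0.05, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def brute_force_clusters(pos, window):
    """Independent oracle: union-find transitive closure of the
    <= window pairwise adjacency between SNP positions."""
    pos = sorted(pos)
    parent = list(range(len(pos)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            if abs(pos[i] - pos[j]) <= window:
                parent[find(i)] = find(j)
    clusters = {}
    for i, p in enumerate(pos):
        clusters.setdefault(find(i), []).append(p)
    return sorted((min(c), max(c)) for c in clusters.values())
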