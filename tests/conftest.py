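import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from popfound import GenotypeMatrix, PopulationMap

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(
    dosages, chrom=None, positions=None, sample_ids=None
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a nested list, defaulting coordinates."""
    d = np.asarray(dosages, dtype=np.int8)
    n, s = d.shape
    return GenotypeMatrix(
        dosages=d,
        chrom=np.array(chrom if chrom is not None else ["chr1"] * s, dtype=object),
        positions=np.array(
            positions if positions is not None else np.arange(1, s + 1) * 100
        ),
        sample_ids=sample_ids or [f"s{i}" for i in range(n)],
    )


def random_matrix(rng, n_samples=8, n_sites=40, missing_rate=0.1) -> GenotypeMatrix:
    d = rng.integers(0, 3, size=(n_samples, n_sites)).astype(np.int8)
    if missing_rate:
        d[rng.random(d.shape) < missing_rate] = -1
    return make_matrix(d)


def bn_pair(f, n_per_pop, n_sites, seed, spacing=200):
    """Two independent Balding-Nichols populations with equal F (no missing)."""
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(0.05, 0.95, size=n_sites)
    scale = (1.0 - f) / f
    pa = rng.beta(p0 * scale, (1.0 - p0) * scale)
    pb = rng.beta(p0 * scale, (1.0 - p0) * scale)
    da = rng.binomial(2, pa, size=(n_per_pop, n_sites))
    db = rng.binomial(2, pb, size=(n_per_pop, n_sites))
    g = make_matrix(
        np.vstack([da, db]),
        positions=np.arange(1, n_sites + 1) * spacing,
        sample_ids=[f"a{i}" for i in range(n_per_pop)] + [f"b{i}" for i in range(n_per_pop)],
    )
    pops = PopulationMap(
        {f"a{i}": "A" for i in range(n_per_pop)} | {f"b{i}": "B" for i in range(n_per_pop)}
    )
    return g, pops


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scenario():
    from popfound import ScenarioConfig, simulate_unlinked

    return simulate_unlinked(ScenarioConfig(n_sites=1200, seed=99))
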