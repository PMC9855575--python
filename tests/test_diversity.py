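import itertools

import numpy as np
import pytest

from popfound import (
    MISSING,
    PopulationMap,
    heterozygosity,
    make_windows,
    site_pi,
    tajima_constants,
    tajima_d,
    window_diversity,
)
from popfound.diversity import Window

from conftest import make_matrix, random_matrix


@pytest.mark.parametrize(
    "length,window,step,expected_starts",
    [
        (25_000, 10_000, 5_000, [0, 5_000, 10_000, 15_000]),
        (9_999, 10_000, 5_000, []),
        (20_000, 10_000, 10_000, [0, 10_000]),  # step == window: tiling
    ],
)
def test_make_windows_enumeration(length, window, step, expected_starts):
    windows = make_windows({"chr1": length}, window, step)
    assert [w.start for w in windows] == expected_starts
    assert all(w.end - w.start == window for w in windows)


@pytest.mark.parametrize(
    "c,n2,expected",
    [(2, 4, 8 / 12), (0, 10, 0.0), (10, 10, 0.0), (1, 2, 1.0)],
)
def test_site_pi_arithmetic(c, n2, expected):
    assert site_pi(c, n2) == pytest.approx(expected)


def test_site_pi_needs_two_alleles():
    assert site_pi(0, 1) is None


def test_tajima_constants_frozen_n4():
    """Hand-evaluated Tajima (1989) constants for n = 4 alleles."""
    k = tajima_constants(4)
    assert k["a1"] == pytest.approx(1.833333, abs=1e-6)
    assert k["e1"] == pytest.approx(0.005510, abs=5e-6)
    assert k["e2"] == pytest.approx(0.002692, abs=5e-6)


def test_tajima_d_single_singleton_toy():
    """S=1, n=4 alleles, site pi=2/3 gives D ~ 1.63."""
    assert tajima_d(2 / 3, 1, 4) == pytest.approx(1.63, abs=0.005)


def test_tajima_d_null_when_no_segregating_sites():
    assert tajima_d(0.0, 0, 10) is None


def _allele_pair_pi(column):
    """Brute-force per-site pi: mismatch fraction over all pairs of called alleles."""
    alleles = []
    for dos in column:
        if dos == MISSING:
            continue
        alleles += {0: [0, 0], 1: [0, 1], 2: [1, 1]}[int(dos)]
    if len(alleles) < 2:
        return 0.0
    pairs = list(itertools.combinations(alleles, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


def test_window_theta_pi_matches_pairwise_oracle(rng):
    """Windowed theta_pi equals O(n^2) allele-pair mismatch counting."""
    g = random_matrix(rng, n_samples=9, n_sites=200, missing_rate=0.15)
    pops = PopulationMap({s: "all" for s in g.sample_ids})
    windows = [Window("chr1", 0, 200 * 100 + 100)]
    (rec,) = window_diversity(g, pops, windows)
    brute = sum(_allele_pair_pi(g.dosages[:, j]) for j in range(g.n_sites))
    assert rec.theta_pi == pytest.approx(brute / windows[0].size, rel=1e-12)


def test_monomorphic_window_yields_zero_theta_null_d():
    g = make_matrix(np.full((4, 5), 2))
    pops = PopulationMap({s: "all" for s in g.sample_ids})
    (rec,) = window_diversity(g, pops, [Window("chr1", 0, 1000)])
    assert rec.theta_w == 0.0
    assert rec.theta_pi == 0.0
    assert rec.tajima_d is None


def test_window_without_data_emits_nulls():
    g = make_matrix([[0, 1], [1, 0]])
    pops = PopulationMap({"s0": "all", "s1": "all"})
    (rec,) = window_diversity(g, pops, [Window("chr2", 0, 1000)])
    assert rec.n_sites == 0
    assert rec.theta_w is None and rec.theta_pi is None and rec.tajima_d is None


def test_heterozygosity_matches_brute_force(rng):
    g = random_matrix(rng, n_samples=10, n_sites=80, missing_rate=0.2)
    pops = PopulationMap(
        {s: ("A" if i < 5 else "B") for i, s in enumerate(g.sample_ids)}
    )
    result = heterozygosity(g, pops)
    alt_all, tot_all = g.allele_counts()
    poly = (alt_all > 0) & (alt_all < tot_all)
    for pop, rows in (("A", range(5)), ("B", range(5, 10))):
        hes, hos = [], []
        for j in np.flatnonzero(poly):
            col = g.dosages[list(rows), j]
            called = col[col != MISSING]
            if called.size == 0:
                continue
            p = called.sum() / (2 * called.size)
            hes.append(2 * p * (1 - p))
            hos.append((called == 1).sum() / called.size)
        assert result[pop][0] == pytest.approx(np.mean(hes))
        assert result[pop][1] == pytest.approx(np.mean(hos))


def test_heterozygosity_trivial_values():
    # p = 0.5 -> He = 0.5; genotypes (0,1,1,2) -> Ho = 0.5
    g = make_matrix([[0], [1], [1], [2]])
    pops = PopulationMap({s: "all" for s in g.sample_ids})
    he, ho = heterozygosity(g, pops)["all"]
    assert he == pytest.approx(0.5)
    assert ho == pytest.approx(0.5)


def test_missing_population_raises(small_scenario):
    g, pops, _ = small_scenario
    with pytest.raises(KeyError):
        window_diversity(g, pops, [Window("chr1", 0, 10_000)], populations=["nope"])


def test_per_variant_mode_rescales_by_site_count(rng):
    g = random_matrix(rng, n_samples=8, n_sites=50, missing_rate=0.0)
    pops = PopulationMap({s: "all" for s in g.sample_ids})
    w = [Window("chr1", 0, 100 * 50 + 100)]
    (per_bp,) = window_diversity(g, pops, w)
    (per_var,) = window_diversity(g, pops, w, per_variant=True)
    assert per_var.theta_pi == pytest.approx(per_bp.theta_pi * w[0].size / 50)
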