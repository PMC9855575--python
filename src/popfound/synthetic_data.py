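"""Synthetic genotype data with the study's 4-population founder-event design.

Two generators:

``simulate_unlinked``
    Balding–Nichols draws for three drifted native populations plus an
    introduced population founded by a small bottleneck from one native
    source, then binomial drift. Sites are unlinked, so analytic
    expectations (FST ~ F, one-generation founder heterozygosity loss
    ``1 - 1/(2*N_f)``) are exact — every downstream test can be a
    parameter-recovery test against the emitted truth record.

``simulate_linked``
    A forward diploid Wright–Fisher population with recombination and
    finite-sites biallelic mutation, for LD-decay analyses where linkage
    matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, PopulationMap

logger = logging.getLogger("popfound")

#: Population labels mirroring the four study sites (three native, one
#: introduced), in the order of ``n_per_pop``.
DEFAULT_LABELS = ("Zhanjiang", "Lingshui", "Haiphong", "Mischief")


@dataclass
class ScenarioConfig:
    """Demographic parameters of the 4-population founder-event scenario.

    Three native populations drift independently from a shared ancestral
    allele frequency under the Balding–Nichols model with per-population
    differentiation ``f_values``; the introduced population is founded from
    ``source_pop`` by ``founder_size`` diploids and then drifts for
    ``post_founding_generations`` at size ``n_intro``.

    Defaults echo the study design: sample sizes 24/14/18/18, F values
    giving pairwise FST on the 0.04–0.12 scale, a founder bottleneck of 10
    diploids and a couple of generations of post-founding drift.
    """

    n_per_pop: tuple[int, ...] = (24, 14, 18, 18)
    labels: tuple[str, ...] = DEFAULT_LABELS
    n_sites: int = 5000
    f_values: tuple[float, ...] = (0.07, 0.05, 0.10)
    source_pop: str = "Lingshui"
    founder_size: int = 10
    post_founding_generations: int = 2
    n_intro: int = 500
    missing_rate: float = 0.05
    seed: int = 0
    # chromosome layout for the emitted VCF coordinates
    n_chroms: int = 2
    site_spacing_bp: int = 200

    def __post_init__(self) -> None:
        if len(self.n_per_pop) != len(self.labels):
            raise ValueError("n_per_pop and labels must have equal length")
        if len(self.f_values) != len(self.labels) - 1:
            raise ValueError("need one F value per native population")
        if self.source_pop not in self.labels[:-1]:
            raise ValueError("source_pop must be one of the native labels")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.founder_size < 1 or self.n_sites < 1:
            raise ValueError("founder_size and n_sites must be positive")

    @property
    def native_labels(self) -> tuple[str, ...]:
        return self.labels[:-1]

    @property
    def introduced_label(self) -> str:
        return self.labels[-1]


@dataclass
class ScenarioTruth:
    """Latent allele frequencies behind a simulated scenario."""

    p_ancestral: np.ndarray
    p_pop: dict[str, np.ndarray]  # per-population per-site frequency

    def to_dataframe(self) -> pd.DataFrame:
        data = {"p_ancestral": self.p_ancestral}
        data.update({f"p_{k}": v for k, v in self.p_pop.items()})
        return pd.DataFrame(data)

    def expected_heterozygosity(self, population: str) -> float:
        p = self.p_pop[population]
        return float(np.mean(2.0 * p * (1.0 - p)))


def _site_coordinates(cfg: ScenarioConfig) -> tuple[np.ndarray, np.ndarray]:
    per_chrom = int(np.ceil(cfg.n_sites / cfg.n_chroms))
    chroms, positions = [], []
    placed = 0
    for c in range(cfg.n_chroms):
        k = min(per_chrom, cfg.n_sites - placed)
        chroms.extend([f"chr{c + 1}"] * k)
        positions.extend(cfg.site_spacing_bp * (np.arange(k) + 1))
        placed += k
    return np.array(chroms, dtype=object), np.array(positions, dtype=np.int64)


def simulate_unlinked(
    cfg: ScenarioConfig,
) -> tuple[GenotypeMatrix, PopulationMap, ScenarioTruth]:
    """Draw an unlinked-SNP genotype dataset for the founder scenario.

    Per site: the ancestral frequency is Uniform(0.05, 0.95); each native
    population's frequency is Beta(p0(1-F)/F, (1-p0)(1-F)/F) (the
    Balding–Nichols model; the F -> 0 limit degenerates to p0 itself); the
    introduced population starts from a binomial founder draw of
    ``2*founder_size`` alleles from the source frequency, followed by
    ``post_founding_generations`` rounds of binomial drift at size
    ``n_intro``. Genotypes are Binomial(2, p) per sample (HWE) and missing
    genotypes are dropped i.i.d. at ``missing_rate``.
    """
    rng = np.random.default_rng(cfg.seed)
    s = cfg.n_sites
    p0 = rng.uniform(0.05, 0.95, size=s)

    p_pop: dict[str, np.ndarray] = {}
    for label, f in zip(cfg.native_labels, cfg.f_values):
        if f <= 0.0:
            p_pop[label] = p0.copy()  # zero-drift limit of the Beta
        else:
            scale = (1.0 - f) / f
            p_pop[label] = rng.beta(p0 * scale, (1.0 - p0) * scale)

    p = rng.binomial(2 * cfg.founder_size, p_pop[cfg.source_pop]) / (2.0 * cfg.founder_size)
    for _ in range(cfg.post_founding_generations):
        p = rng.binomial(2 * cfg.n_intro, p) / (2.0 * cfg.n_intro)
    p_pop[cfg.introduced_label] = p

    dosage_blocks = []
    assignments: dict[str, str] = {}
    for label, n in zip(cfg.labels, cfg.n_per_pop):
        dosage_blocks.append(rng.binomial(2, p_pop[label], size=(n, s)))
        for i in range(n):
            assignments[f"{label}_{i + 1:02d}"] = label
    dosages = np.concatenate(dosage_blocks, axis=0).astype(np.int8)

    if cfg.missing_rate > 0:
        drop = rng.random(dosages.shape) < cfg.missing_rate
        dosages[drop] = MISSING

    chroms, positions = _site_coordinates(cfg)
    g = GenotypeMatrix(
        dosages=dosages,
        chrom=chroms,
        positions=positions,
        sample_ids=list(assignments),
    )
    return g, PopulationMap(assignments), ScenarioTruth(p_ancestral=p0, p_pop=p_pop)


@dataclass
class WrightFisherConfig:
    """Parameters of the forward Wright–Fisher simulator.

    ``pop_size`` diploids, a single chromosome of ``chrom_length_bp`` sites,
    per-bp per-generation mutation rate ``mu`` (biallelic flips; a repeat
    mutation at a site toggles it back) and recombination rate ``rec``
    (crossover count per gamete ~ Poisson(rec * L), breakpoints uniform).
    """

    pop_size: int = 100
    chrom_length_bp: int = 20_000
    mu: float = 1.25e-5
    rec: float = 1e-4
    burn_in_generations: int = 1000
    sample_size: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.burn_in_generations < 0:
            raise ValueError("burn_in_generations must be >= 0")
        if not 1 <= self.sample_size <= self.pop_size:
            raise ValueError("sample_size must be in [1, pop_size]")


def _next_generation(
    hap: np.ndarray, n: int, length: int, rec: float, mu: float, rng: np.random.Generator
) -> np.ndarray:
    n_h = 2 * n
    parents = rng.integers(0, n, size=n_h)
    start = rng.integers(0, 2, size=n_h)
    k = rng.poisson(rec * length, size=n_h) if rec > 0 else np.zeros(n_h, dtype=np.int64)
    total = int(k.sum())
    all_bps = rng.integers(0, length, size=total)
    offsets = np.concatenate([[0], np.cumsum(k)])

    off = np.empty_like(hap)
    for gam in range(n_h):
        h0 = hap[2 * parents[gam]]
        h1 = hap[2 * parents[gam] + 1]
        cur = int(start[gam])
        if k[gam] == 0:
            off[gam] = h1 if cur else h0
            continue
        bps = np.sort(all_bps[offsets[gam] : offsets[gam + 1]])
        row = off[gam]
        prev = 0
        for b in bps:  # copy alternating parental segments
            row[prev:b] = (h1 if cur else h0)[prev:b]
            cur ^= 1
            prev = b
        row[prev:] = (h1 if cur else h0)[prev:]
    n_mut = rng.poisson(mu * length * n_h)
    if n_mut:
        mr = rng.integers(0, n_h, size=n_mut)
        mc = rng.integers(0, length, size=n_mut)
        np.bitwise_xor.at(off, (mr, mc), 1)
    return off


def simulate_linked(cfg: WrightFisherConfig) -> GenotypeMatrix:
    """Run the forward Wright–Fisher simulator and sample genotypes.

    Starts monomorphic, evolves for ``burn_in_generations``, then samples
    ``sample_size`` diploids. Only sites segregating in the sample are
    emitted; positions are the 1-based site coordinates on "chr1".
    """
    rng = np.random.default_rng(cfg.seed)
    n, length = cfg.pop_size, cfg.chrom_length_bp
    hap = np.zeros((2 * n, length), dtype=np.uint8)
    for _ in range(cfg.burn_in_generations):
        hap = _next_generation(hap, n, length, cfg.rec, cfg.mu, rng)

    chosen = rng.choice(n, size=cfg.sample_size, replace=False)
    chosen.sort()
    genotypes = (hap[2 * chosen] + hap[2 * chosen + 1]).astype(np.int8)

    seg = np.flatnonzero(
        (genotypes.sum(axis=0) > 0) & (genotypes.sum(axis=0) < 2 * cfg.sample_size)
    )
    if seg.size == 0:
        logger.warning("simulate_linked: no segregating sites in the sample")
    sample_ids = [f"wf_{i + 1:03d}" for i in range(cfg.sample_size)]
    return GenotypeMatrix(
        dosages=genotypes[:, seg],
        chrom=np.array(["chr1"] * seg.size, dtype=object),
        positions=seg.astype(np.int64) + 1,
        sample_ids=sample_ids,
    )


def single_population_map(g: GenotypeMatrix, label: str = "pop") -> PopulationMap:
    """Trivial map placing every sample of ``g`` in one population."""
    return PopulationMap({s: label for s in g.sample_ids})


def inject_sweep(
    g: GenotypeMatrix,
    pops: PopulationMap,
    population: str,
    chrom: str,
    start: int,
    end: int,
) -> GenotypeMatrix:
    """Overwrite one population's genotypes in a region with a hard-sweep pattern.

    Within the 0-based half-open [start, end) block on ``chrom``, every
    sample of ``population`` becomes homozygous reference except a single
    heterozygous carrier per site (a swept region recovering rare variants):
    diversity collapses while each site keeps one singleton, so the site
    frequency spectrum in the block is all-rare. Returns a modified copy.
    """
    idx = pops.indices_of(population, g.sample_ids)
    pos0 = g.positions - 1
    sites = np.flatnonzero((g.chrom == chrom) & (pos0 >= start) & (pos0 < end))
    dosages = g.dosages.copy()
    for k, j in enumerate(sites):
        dosages[idx, j] = 0
        dosages[idx[k % idx.size], j] = 1  # rotate the singleton carrier
    return GenotypeMatrix(
        dosages=dosages,
        chrom=g.chrom.copy(),
        positions=g.positions.copy(),
        sample_ids=list(g.sample_ids),
        site_ids=list(g.site_ids),
    )
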