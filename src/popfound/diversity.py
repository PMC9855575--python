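"""Per-population diversity: He/Ho and sliding-window theta_w, theta_pi, Tajima's D.

Window statistics follow the classical estimators on a biallelic dosage
matrix. Within a window of L bp and a population with (rounded mean) n
non-missing alleles across sites:

    theta_w  = S / (a1 * L),        a1 = sum_{i<n} 1/i
    theta_pi = sum_sites 2c(2m-c) / (2m(2m-1)) / L
    Tajima's D = (pi_sum - S/a1) / sqrt(e1*S + e2*S*(S-1))

with S the count of sites segregating within the population and e1, e2 the
Tajima (1989) normalising constants. The window denominator L is the full
window span in bp by default; ``per_variant=True`` divides by the number of
sites with data instead (useful when callable-site density is unknown).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import sqrt

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, PopulationMap

logger = logging.getLogger("popfound")


@dataclass(frozen=True)
class Window:
    """Genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    @property
    def size(self) -> int:
        return self.end - self.start


def make_windows(
    chrom_lengths: dict[str, int], window_size: int = 10_000, step: int = 5_000
) -> list[Window]:
    """Sliding windows starting at 0, ``step`` apart, fully inside each chromosome.

    A trailing region shorter than ``window_size`` produces no window; a
    chromosome shorter than ``window_size`` yields none (logged).
    """
    if not (window_size >= step >= 1):
        raise ValueError("require window_size >= step >= 1")
    windows: list[Window] = []
    for chrom, length in chrom_lengths.items():
        if length < window_size:
            logger.info("make_windows: %s shorter than one window, skipped", chrom)
            continue
        for start in range(0, length - window_size + 1, step):
            windows.append(Window(chrom, start, start + window_size))
    return windows


def chrom_lengths_from_matrix(g: GenotypeMatrix) -> dict[str, int]:
    """Chromosome extents implied by the largest observed position."""
    out: dict[str, int] = {}
    for c, p in zip(g.chrom, g.positions):
        out[c] = max(out.get(c, 0), int(p))
    return out


def site_pi(allele_count: int, n_alleles: int) -> float | None:
    """Unbiased per-site nucleotide diversity 2c(2n-c) / (2n(2n-1)).

    ``allele_count`` is the ALT-allele count c and ``n_alleles`` the number
    of non-missing alleles (2n). Returns None when fewer than 2 alleles are
    called.
    """
    if n_alleles < 2:
        return None
    if not 0 <= allele_count <= n_alleles:
        raise ValueError("allele_count must be within [0, n_alleles]")
    return 2.0 * allele_count * (n_alleles - allele_count) / (n_alleles * (n_alleles - 1.0))


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalising constants for n sampled alleles."""
    if n < 2:
        raise ValueError("need at least 2 alleles")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_d(pi_sum: float, n_segregating: int, n_alleles: int) -> float | None:
    """Tajima's D from the summed per-site pi, S and the allele count n."""
    if n_segregating == 0 or n_alleles < 2:
        return None
    k = tajima_constants(n_alleles)
    s = float(n_segregating)
    var = k["e1"] * s + k["e2"] * s * (s - 1.0)
    if var <= 0:
        return None
    return (pi_sum - s / k["a1"]) / sqrt(var)


def _pop_site_arrays(
    g: GenotypeMatrix, pops: PopulationMap, population: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (ALT count, non-missing allele count) within one population."""
    idx = pops.indices_of(population, g.sample_ids)
    return g.allele_counts(sample_index=idx)


def _window_site_index(g: GenotypeMatrix, windows: list[Window]) -> list[np.ndarray]:
    """Site indices falling in each window (VCF pos p -> 0-based p-1)."""
    pos0 = g.positions - 1
    out = []
    order = np.arange(g.n_sites)
    for w in windows:
        in_w = (g.chrom == w.chrom) & (pos0 >= w.start) & (pos0 < w.end)
        out.append(order[in_w])
    return out


@dataclass
class WindowDiversity:
    """Diversity statistics for one window and one population."""

    window: Window
    population: str
    n_sites: int
    n_segregating: int
    theta_w: float | None
    theta_pi: float | None
    tajima_d: float | None


def window_diversity(
    g: GenotypeMatrix,
    pops: PopulationMap,
    windows: list[Window],
    populations: list[str] | None = None,
    per_variant: bool = False,
) -> list[WindowDiversity]:
    """Sliding-window theta_w, theta_pi and Tajima's D per population.

    ``per_variant=True`` normalises theta by the count of sites with data in
    the window rather than the window span in bp.
    """
    populations = populations or pops.populations
    site_idx = _window_site_index(g, windows)
    records: list[WindowDiversity] = []
    for population in populations:
        alt, tot = _pop_site_arrays(g, pops, population)
        with np.errstate(invalid="ignore", divide="ignore"):
            pi_site = np.where(
                tot >= 2, 2.0 * alt * (tot - alt) / np.maximum(tot * (tot - 1.0), 1.0), np.nan
            )
        seg = (tot >= 2) & (alt > 0) & (alt < tot)
        for w, idx in zip(windows, site_idx):
            usable = idx[tot[idx] >= 2]
            n_with_data = int(usable.size)
            s = int(seg[idx].sum())
            if n_with_data == 0:
                records.append(
                    WindowDiversity(w, population, 0, 0, None, None, None)
                )
                continue
            denom = float(n_with_data) if per_variant else float(w.size)
            pi_sum = float(np.nansum(pi_site[usable]))
            n_mean = int(round(float(tot[usable].mean())))
            theta_w = None
            d = None
            if n_mean >= 2:
                a1 = tajima_constants(n_mean)["a1"]
                theta_w = s / (a1 * denom)
                d = tajima_d(pi_sum, s, n_mean)
            records.append(
                WindowDiversity(
                    w, population, n_with_data, s, theta_w, pi_sum / denom, d
                )
            )
    return records


@dataclass
class PopDiversitySummary:
    """Genome-wide diversity summary for one population."""

    population: str
    he: float
    ho: float
    theta_w: float
    theta_pi: float
    tajima_d: float | None


def heterozygosity(
    g: GenotypeMatrix, pops: PopulationMap, populations: list[str] | None = None
) -> dict[str, tuple[float, float]]:
    """Per-population mean expected and observed heterozygosity.

    He_site = 2p(1-p) with p from the population's non-missing alleles;
    Ho_site = heterozygote fraction among its non-missing genotypes. Both are
    averaged over sites polymorphic in the full dataset; sites without data
    in a population are skipped there.
    """
    if g.n_sites == 0:
        raise ValueError("empty genotype matrix")
    populations = populations or pops.populations
    alt_all, tot_all = g.allele_counts()
    poly = (alt_all > 0) & (alt_all < tot_all)

    out: dict[str, tuple[float, float]] = {}
    for population in populations:
        idx = pops.indices_of(population, g.sample_ids)
        d = g.dosages[idx, :]
        called = d != -1
        n_geno = called.sum(axis=0)
        alt = np.where(called, d, 0).sum(axis=0)
        tot = 2 * n_geno
        use = poly & (tot >= 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt[use] / tot[use]
            he = 2.0 * p * (1.0 - p)
            ho = (d[:, use] == 1).sum(axis=0) / n_geno[use]
        out[population] = (float(np.mean(he)), float(np.mean(ho)))
    return out


def diversity_summary(
    g: GenotypeMatrix,
    pops: PopulationMap,
    windows: list[Window],
    per_variant: bool = False,
) -> list[PopDiversitySummary]:
    """Genome-wide per-population summary (the study's Table-1 layout).

    theta_w and theta_pi are unweighted means over windows with data;
    Tajima's D is the unweighted mean over windows where it is defined.
    """
    het = heterozygosity(g, pops)
    wd = window_diversity(g, pops, windows, per_variant=per_variant)
    rows: list[PopDiversitySummary] = []
    for population in pops.populations:
        recs = [r for r in wd if r.population == population]
        tw = [r.theta_w for r in recs if r.theta_w is not None]
        tp = [r.theta_pi for r in recs if r.theta_pi is not None]
        td = [r.tajima_d for r in recs if r.tajima_d is not None]
        he, ho = het[population]
        rows.append(
            PopDiversitySummary(
                population=population,
                he=he,
                ho=ho,
                theta_w=float(np.mean(tw)) if tw else 0.0,
                theta_pi=float(np.mean(tp)) if tp else 0.0,
                tajima_d=float(np.mean(td)) if td else None,
            )
        )
    return rows


def window_diversity_frame(records: list[WindowDiversity]) -> pd.DataFrame:
    """Tabular view: chrom, start, end, pop, n_sites, theta_w, theta_pi, tajima_d."""
    return pd.DataFrame(
        {
            "chrom": [r.window.chrom for r in records],
            "start": [r.window.start for r in records],
            "end": [r.window.end for r in records],
            "pop": [r.population for r in records],
            "n_sites": [r.n_sites for r in records],
            "n_segregating": [r.n_segregating for r in records],
            "theta_w": [r.theta_w for r in records],
            "theta_pi": [r.theta_pi for r in records],
            "tajima_d": [r.tajima_d for r in records],
        }
    )


def summary_frame(rows: list[PopDiversitySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pop": [r.population for r in rows],
            "He": [r.he for r in rows],
            "Ho": [r.ho for r in rows],
            "theta_w": [r.theta_w for r in rows],
            "theta_pi": [r.theta_pi for r in rows],
            "tajima_d": [r.tajima_d for r in rows],
        }
    )
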