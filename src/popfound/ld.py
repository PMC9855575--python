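"""Linkage disequilibrium: pairwise dosage r-squared and binned decay curves.

r-squared here is the squared Pearson correlation of unphased ALT-dosage
vectors (the composite measure), computed over samples called at both sites.
Decay curves average r-squared in half-open distance bins over all (or a
seeded subsample of) intra-chromosome site pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, PopulationMap

logger = logging.getLogger("popfound")


def pair_r2(g_i: np.ndarray, g_j: np.ndarray) -> float | None:
    """Squared Pearson correlation of two dosage vectors.

    Samples missing (dosage < 0) at either site are dropped; returns None
    when fewer than 2 shared samples remain or either site is monomorphic
    among them.
    """
    g_i = np.asarray(g_i, dtype=float)
    g_j = np.asarray(g_j, dtype=float)
    ok = (g_i >= 0) & (g_j >= 0)
    if ok.sum() < 2:
        return None
    x, y = g_i[ok], g_j[ok]
    vx, vy = x.var(), y.var()
    if vx == 0.0 or vy == 0.0:
        return None
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov**2 / (vx * vy))


@dataclass
class LDDecayCurve:
    """Mean r-squared per half-open distance bin for one population."""

    population: str
    bin_edges: np.ndarray  # len n_bins + 1
    mean_r2: np.ndarray  # len n_bins, NaN for empty bins
    n_pairs: np.ndarray  # len n_bins

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "population": self.population,
                "bin_lo": self.bin_edges[:-1].astype(int),
                "bin_hi": self.bin_edges[1:].astype(int),
                "mean_r2": self.mean_r2,
                "n_pairs": self.n_pairs.astype(int),
            }
        )


def _eligible_pairs(
    g: GenotypeMatrix, max_dist: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Intra-chromosome site index pairs with 0 < distance <= max_dist."""
    ii, jj, dd = [], [], []
    for chrom in pd.unique(g.chrom):
        idx = np.flatnonzero(g.chrom == chrom)
        pos = g.positions[idx]
        # sites are position-sorted within chromosomes; walk a distance window
        start = 0
        for k in range(len(idx)):
            while pos[k] - pos[start] > max_dist:
                start += 1
            for l in range(start, k):
                ii.append(idx[l])
                jj.append(idx[k])
                dd.append(int(pos[k] - pos[l]))
    return np.array(ii, dtype=np.int64), np.array(jj, dtype=np.int64), np.array(dd, dtype=np.int64)


def ld_decay(
    g: GenotypeMatrix,
    pops: PopulationMap,
    population: str,
    max_dist: int = 50_000,
    bin_width: int = 5_000,
    max_pairs: int = 1_000_000,
    seed: int = 0,
) -> LDDecayCurve:
    """Binned LD-decay curve for one population.

    All intra-chromosome pairs within ``max_dist`` are used, subsampled
    (seeded) to ``max_pairs`` when more exist; pairs where r-squared is
    undefined are excluded from the bins.
    """
    idx = pops.indices_of(population, g.sample_ids)
    if idx.size < 2:
        raise ValueError("population needs >= 2 samples")
    ii, jj, dd = _eligible_pairs(g, max_dist)
    edges = np.arange(0, max_dist + bin_width, bin_width)
    n_bins = len(edges) - 1
    if ii.size == 0:
        logger.warning("ld_decay: no eligible site pairs within %d bp", max_dist)
        return LDDecayCurve(population, edges, np.full(n_bins, np.nan), np.zeros(n_bins))

    if ii.size > max_pairs:
        pick = np.random.default_rng(seed).choice(ii.size, size=max_pairs, replace=False)
        ii, jj, dd = ii[pick], jj[pick], dd[pick]

    d = g.dosages[idx, :].astype(float)
    d[d < 0] = np.nan

    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    bins = np.minimum(dd // bin_width, n_bins - 1)  # dd == max_dist lands in last bin
    mask = (~np.isnan(d)).astype(float)
    x0 = np.nan_to_num(d)
    chunk = 200_000
    for lo in range(0, ii.size, chunk):
        a, b = ii[lo : lo + chunk], jj[lo : lo + chunk]
        # pairwise-complete sums: restrict each moment to samples called at both sites
        ma, mb = mask[:, a], mask[:, b]
        xa, xb = x0[:, a], x0[:, b]
        both = ma * mb
        n = both.sum(axis=0)
        sx = (xa * both).sum(axis=0)
        sy = (xb * both).sum(axis=0)
        sxx = (xa * xa * both).sum(axis=0)
        syy = (xb * xb * both).sum(axis=0)
        sxy = (xa * xb * both).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            vx = n * sxx - sx * sx
            vy = n * syy - sy * sy
            cov = n * sxy - sx * sy
            r2 = cov**2 / (vx * vy)
        ok = (n >= 2) & (vx > 0) & (vy > 0)
        np.add.at(sums, bins[lo : lo + chunk][ok], r2[ok])
        np.add.at(counts, bins[lo : lo + chunk][ok], 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LDDecayCurve(population, edges, mean_r2, counts)
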