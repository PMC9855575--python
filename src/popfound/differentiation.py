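"""Pairwise FST: Hudson and Weir–Cockerham estimators, windowed and global.

Both estimators accumulate per-site components and report ratio-of-sums
values (never means of per-site ratios), which is the numerically stable
aggregation for sparse windows.

Hudson (Bhatia et al. parameterisation), per site with sample allele
frequencies p1, p2 and non-missing allele counts n1, n2:

    N = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    D = p1(1-p2) + p2(1-p1)
    FST = sum(N) / sum(D)

Weir & Cockerham (1984) uses the two-population variance components a, b, c
computed from genotype counts (including observed heterozygosity), with
FST = sum(a) / sum(a+b+c).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import Window, _window_site_index
from .genotype_io import GenotypeMatrix, PopulationMap

logger = logging.getLogger("popfound")

ESTIMATORS = ("weir_cockerham", "hudson")


@dataclass
class FstResult:
    """Pairwise FST between two populations, global and per window."""

    pop_a: str
    pop_b: str
    estimator: str
    global_fst: float | None
    window_fst: list[float | None]

    def clipped_windows(self) -> list[float | None]:
        """Window values clipped to the report range [-1, 1]."""
        return [None if v is None else float(np.clip(v, -1.0, 1.0)) for v in self.window_fst]


def _hudson_components(
    alt_a: np.ndarray, tot_a: np.ndarray, alt_b: np.ndarray, tot_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Hudson numerator/denominator and a usable-site mask.

    Sites need >= 2 alleles in each population (the n-1 bias correction)."""
    ok = (tot_a >= 2) & (tot_b >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(ok, alt_a / np.maximum(tot_a, 1), np.nan)
        p2 = np.where(ok, alt_b / np.maximum(tot_b, 1), np.nan)
        num = (
            (p1 - p2) ** 2
            - p1 * (1.0 - p1) / np.maximum(tot_a - 1, 1)
            - p2 * (1.0 - p2) / np.maximum(tot_b - 1, 1)
        )
        den = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    return np.where(ok, num, 0.0), np.where(ok, den, 0.0), ok


def _wc_components(
    g: GenotypeMatrix, idx_a: np.ndarray, idx_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir–Cockerham (1984) a, a+b+c for two populations."""
    comp_a = np.zeros(g.n_sites)
    comp_abc = np.zeros(g.n_sites)
    r = 2.0

    d_a = g.dosages[idx_a, :]
    d_b = g.dosages[idx_b, :]
    n_i = np.stack([(d_a != -1).sum(axis=0), (d_b != -1).sum(axis=0)]).astype(float)
    alt_i = np.stack(
        [np.where(d_a != -1, d_a, 0).sum(axis=0), np.where(d_b != -1, d_b, 0).sum(axis=0)]
    ).astype(float)
    het_i = np.stack([(d_a == 1).sum(axis=0), (d_b == 1).sum(axis=0)]).astype(float)

    ok = (n_i >= 1).all(axis=0) & (n_i.sum(axis=0) >= 3)  # n_bar > 1 required
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = alt_i / (2.0 * n_i)
        h_i = het_i / n_i
        n_bar = n_i.mean(axis=0)
        n_c = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1.0)
        p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1.0) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)

        a = (n_bar / n_c) * (
            s2
            - (p_bar * (1.0 - p_bar) - s2 * (r - 1.0) / r - h_bar / 4.0) / (n_bar - 1.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar)
            - s2 * (r - 1.0) / r
            - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
        )
        c = h_bar / 2.0

    comp_a[ok] = a[ok]
    comp_abc[ok] = (a + b + c)[ok]
    # monomorphic-across-both sites contribute 0/0; keep their zeros
    return comp_a, comp_abc, ok


def fst_pair(
    g: GenotypeMatrix,
    pops: PopulationMap,
    pop_a: str,
    pop_b: str,
    windows: list[Window] | None = None,
    estimator: str = "weir_cockerham",
) -> FstResult:
    """Pairwise FST between two populations, global and per window.

    Sites lacking data in either population are skipped. Returns a null
    global value (with a warning) when no usable site exists.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"estimator must be one of {ESTIMATORS}")
    idx_a = pops.indices_of(pop_a, g.sample_ids)
    idx_b = pops.indices_of(pop_b, g.sample_ids)
    if idx_a.size < 2 or idx_b.size < 2:
        raise ValueError("both populations need >= 2 genotyped samples")

    if estimator == "hudson":
        alt_a, tot_a = g.allele_counts(sample_index=idx_a)
        alt_b, tot_b = g.allele_counts(sample_index=idx_b)
        num, den, ok = _hudson_components(alt_a, tot_a, alt_b, tot_b)
    else:
        num, den, ok = _wc_components(g, idx_a, idx_b)

    def ratio(site_index: np.ndarray) -> float | None:
        d = float(den[site_index].sum())
        if not ok[site_index].any() or d == 0.0:
            return None
        return float(num[site_index].sum() / d)

    global_fst = ratio(np.arange(g.n_sites))
    if global_fst is None:
        logger.warning("fst_pair(%s, %s): no usable sites", pop_a, pop_b)

    window_fst: list[float | None] = []
    if windows:
        for idx in _window_site_index(g, windows):
            window_fst.append(ratio(idx) if idx.size else None)

    return FstResult(pop_a, pop_b, estimator, global_fst, window_fst)


def fst_matrix(
    g: GenotypeMatrix,
    pops: PopulationMap,
    windows: list[Window] | None = None,
    estimator: str = "weir_cockerham",
) -> dict[tuple[str, str], FstResult]:
    """All unordered population pairs (C(k,2) of them)."""
    labels = pops.populations
    if len(labels) < 2:
        raise ValueError("need >= 2 populations")
    out: dict[tuple[str, str], FstResult] = {}
    for a, b in itertools.combinations(labels, 2):
        out[(a, b)] = fst_pair(g, pops, a, b, windows=windows, estimator=estimator)
    return out


def fst_matrix_frame(results: dict[tuple[str, str], FstResult], labels: list[str]) -> pd.DataFrame:
    """Lower-triangular pairwise FST table (the study's Table-2 layout)."""
    frame = pd.DataFrame(index=labels, columns=labels, dtype=float)
    for (a, b), res in results.items():
        i, j = labels.index(a), labels.index(b)
        row, col = (a, b) if i > j else (b, a)
        frame.loc[row, col] = np.nan if res.global_fst is None else res.global_fst
    return frame


def window_fst_frame(
    results: dict[tuple[str, str], FstResult], windows: list[Window]
) -> pd.DataFrame:
    rows = []
    for (a, b), res in results.items():
        for w, v in zip(windows, res.clipped_windows()):
            rows.append((w.chrom, w.start, w.end, f"{a}-{b}", v))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "pair", "fst"])
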