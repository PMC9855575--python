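"""Directional relative-migration networks between populations.

For every ordered population pair (a, b) a hypothetical migrant pool with
per-site allele frequency (p_a + p_b)/2 is constructed; the differentiation
between that pool and the recipient b (Nei's Gst, Jost's D, or the classic
Nm transform of Gst) is turned into a raw migration rate into b — lower
pool-vs-recipient differentiation means more migration into the recipient.
The full directed matrix is normalised by its maximum so the strongest edge
is exactly 1, and edges below a filter threshold are flagged (never
deleted). Bootstrap support resamples individuals with replacement within
populations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, PopulationMap

logger = logging.getLogger("popfound")

STATISTICS = ("gst", "jost_d", "nm")


def _gst_jost(
    p_x: np.ndarray, p_pool: np.ndarray
) -> tuple[float | None, float | None]:
    """Nei Gst and Jost's D for the two demes {population x, pool}.

    Per site: Hs is the mean of the two within-deme heterozygosities,
    Ht = 2*pbar*(1-pbar) with pbar the mean of the two frequencies; sums are
    taken over sites before any ratio. Jost's D carries the two-deme
    n/(n-1) = 2 correction.
    """
    hs = 0.5 * (2.0 * p_x * (1.0 - p_x) + 2.0 * p_pool * (1.0 - p_pool))
    pbar = 0.5 * (p_x + p_pool)
    ht = 2.0 * pbar * (1.0 - pbar)
    sum_ht = float(ht.sum())
    if sum_ht == 0.0:
        return None, None
    num = float(ht.sum() - hs.sum())
    gst = num / sum_ht
    denom_d = float((1.0 - hs).sum())
    jost = (num / denom_d) * 2.0 if denom_d > 0 else None
    return gst, jost


def pooled_stats(
    freq_a: np.ndarray, freq_b: np.ndarray, n_a: int, n_b: int
) -> dict[str, tuple[float | None, float | None]]:
    """Pool the pair and return each population's (Gst, Jost's D) vs the pool.

    ``freq_a``/``freq_b`` are per-site allele frequencies on shared sites;
    the pool frequency is their unweighted per-site mean. Sample sizes are
    accepted for interface symmetry (the plug-in estimators ignore them).
    """
    freq_a = np.asarray(freq_a, dtype=float)
    freq_b = np.asarray(freq_b, dtype=float)
    if freq_a.shape != freq_b.shape:
        raise ValueError("frequency vectors must align on shared sites")
    pool = 0.5 * (freq_a + freq_b)
    return {"a": _gst_jost(freq_a, pool), "b": _gst_jost(freq_b, pool)}


@dataclass
class MigrationNetwork:
    """Directed relative-migration matrix with bootstrap summaries."""

    labels: list[str]
    m: np.ndarray  # (k, k); m[a, b] = relative migration a -> b; NaN diagonal
    statistic: str
    filter_threshold: float
    hidden: np.ndarray  # bool (k, k); True where edge < threshold
    boot_mean: np.ndarray | None = None
    boot_ci_low: np.ndarray | None = None
    boot_ci_high: np.ndarray | None = None

    def edge_frame(self) -> pd.DataFrame:
        rows = []
        k = len(self.labels)
        for i in range(k):
            for j in range(k):
                if i == j:
                    continue
                rows.append(
                    (
                        self.labels[i],
                        self.labels[j],
                        self.statistic,
                        self.m[i, j],
                        None if self.boot_ci_low is None else self.boot_ci_low[i, j],
                        None if self.boot_ci_high is None else self.boot_ci_high[i, j],
                        bool(self.hidden[i, j]),
                    )
                )
        return pd.DataFrame(
            rows,
            columns=["from", "to", "statistic", "relative_rate", "boot_ci_low", "boot_ci_high", "hidden"],
        )


def _pop_freqs(
    g: GenotypeMatrix, indices: dict[str, np.ndarray]
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    freqs, totals = {}, {}
    for label, idx in indices.items():
        alt, tot = g.allele_counts(sample_index=idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[label] = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
        totals[label] = tot
    return freqs, totals


def _raw_matrix(
    freqs: dict[str, np.ndarray],
    totals: dict[str, np.ndarray],
    labels: list[str],
    statistic: str,
) -> np.ndarray:
    k = len(labels)
    raw = np.full((k, k), np.nan)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i == j:
                continue
            shared = (totals[a] > 0) & (totals[b] > 0)
            fa, fb = freqs[a][shared], freqs[b][shared]
            pool = 0.5 * (fa + fb)
            gst, jost = _gst_jost(fb, pool)  # differentiation pool vs recipient b
            d = {"gst": gst, "jost_d": jost, "nm": gst}[statistic]
            if d is None:
                raw[i, j] = np.nan
            elif d <= 0.0:
                raw[i, j] = np.inf  # placeholder, capped below
            elif statistic == "nm":
                raw[i, j] = (1.0 / d - 1.0) / 4.0
            else:
                raw[i, j] = (1.0 - d) / d
    inf_mask = np.isinf(raw)
    if inf_mask.any():
        finite = raw[np.isfinite(raw)]
        cap = float(finite.max()) if finite.size else 1.0
        raw[inf_mask] = cap
        logger.info("directional_network: %d zero-differentiation edges capped", int(inf_mask.sum()))
    return raw


def _normalise(raw: np.ndarray) -> np.ndarray:
    top = np.nanmax(raw)
    if not np.isfinite(top) or top <= 0:
        return raw
    return raw / top


def directional_network(
    g: GenotypeMatrix,
    pops: PopulationMap,
    statistic: str = "gst",
    bootstraps: int = 1000,
    filter_threshold: float = 0.2,
    seed: int = 0,
) -> MigrationNetwork:
    """Directional relative-migration network over all ordered pairs.

    ``bootstraps`` resamples of individuals (with replacement, within each
    population) give percentile (2.5/97.5) confidence intervals per edge.
    Edges below ``filter_threshold`` after normalisation are flagged hidden.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    labels = pops.populations
    if len(labels) < 2:
        raise ValueError("need >= 2 populations")
    pops.validate_against(g)
    indices = {label: pops.indices_of(label, g.sample_ids) for label in labels}

    freqs, totals = _pop_freqs(g, indices)
    m = _normalise(_raw_matrix(freqs, totals, labels, statistic))

    boot_mean = ci_low = ci_high = None
    if bootstraps > 0:
        rng = np.random.default_rng(seed)
        stack = np.empty((bootstraps, len(labels), len(labels)))
        for rep in range(bootstraps):
            resampled = {
                label: rng.choice(idx, size=idx.size, replace=True)
                for label, idx in indices.items()
            }
            f_b, t_b = _pop_freqs(g, resampled)
            stack[rep] = _normalise(_raw_matrix(f_b, t_b, labels, statistic))
        diag = np.eye(len(labels), dtype=bool)
        stack[:, diag] = 0.0  # keep nan-aggregations quiet on the diagonal
        boot_mean = np.nanmean(stack, axis=0)
        ci_low = np.nanpercentile(stack, 2.5, axis=0)
        ci_high = np.nanpercentile(stack, 97.5, axis=0)
        for arr in (boot_mean, ci_low, ci_high):
            arr[diag] = np.nan

    hidden = np.zeros_like(m, dtype=bool)
    off = ~np.eye(len(labels), dtype=bool)
    hidden[off] = m[off] < filter_threshold

    return MigrationNetwork(
        labels=labels,
        m=m,
        statistic=statistic,
        filter_threshold=filter_threshold,
        hidden=hidden,
        boot_mean=boot_mean,
        boot_ci_low=ci_low,
        boot_ci_high=ci_high,
    )


def asymmetry_ci(
    g: GenotypeMatrix,
    pops: PopulationMap,
    pop_a: str,
    pop_b: str,
    statistic: str = "gst",
    bootstraps: int = 200,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Bootstrap percentile CI of m[a->b] - m[b->a] (point estimate first).

    A CI covering 0 means no detectable directionality for the pair.
    """
    labels = pops.populations
    ia, ib = labels.index(pop_a), labels.index(pop_b)
    net = directional_network(
        g, pops, statistic=statistic, bootstraps=0, filter_threshold=0.0, seed=seed
    )
    point = float(net.m[ia, ib] - net.m[ib, ia])

    rng = np.random.default_rng(seed)
    indices = {label: pops.indices_of(label, g.sample_ids) for label in labels}
    diffs = np.empty(bootstraps)
    for rep in range(bootstraps):
        resampled = {
            label: rng.choice(idx, size=idx.size, replace=True)
            for label, idx in indices.items()
        }
        f_b, t_b = _pop_freqs(g, resampled)
        mat = _normalise(_raw_matrix(f_b, t_b, labels, statistic))
        diffs[rep] = mat[ia, ib] - mat[ib, ia]
    return point, float(np.nanpercentile(diffs, 2.5)), float(np.nanpercentile(diffs, 97.5))
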