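"""Selection scan for the introduced population: windowed ROD, FST and Tajima's D.

ROD (reduction of diversity) compares windowed nucleotide diversity between
the introduced population and its source: ROD = 1 - theta_pi(introduced) /
theta_pi(source); values near 1 mark windows where the introduced population
lost nearly all diversity. Candidate windows combine empirical-quantile
outlier flags: (FST in the top tail OR ROD in the top tail) AND Tajima's D of
the introduced population in the bottom tail and negative. Overlapping or
book-ended candidate windows merge into candidate regions, which are then
annotated with overlapping genes from a GFF3 file.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd

from .differentiation import fst_pair
from .diversity import Window, window_diversity
from .genotype_io import GenotypeMatrix, PopulationMap

logger = logging.getLogger("popfound")


def rod(theta_pi_intro: float, theta_pi_source: float) -> float | None:
    """Reduction of diversity, 1 - theta_pi(introduced)/theta_pi(source).

    Returns None when the source diversity is 0 (undefined ratio); negative
    diversities are rejected.
    """
    if theta_pi_intro < 0 or theta_pi_source < 0:
        raise ValueError("diversities must be non-negative")
    if theta_pi_source == 0.0:
        return None
    return 1.0 - theta_pi_intro / theta_pi_source


def flag_outliers(
    values: list[float | None], tail: str = "top", fraction: float = 0.05
) -> list[bool]:
    """Flag the empirical ``fraction`` tail of the non-null values by rank.

    ``top`` flags the ceil(fraction * n) largest values, ``bottom`` the
    smallest; ties at the boundary are all included, and nulls are never
    flagged.
    """
    if tail not in ("top", "bottom"):
        raise ValueError("tail must be 'top' or 'bottom'")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    present = [v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))]
    if not present:
        logger.warning("flag_outliers: no non-null values")
        return [False] * len(values)
    k = math.ceil(fraction * len(present))
    ordered = sorted(present, reverse=(tail == "top"))
    threshold = ordered[k - 1]
    if tail == "top":
        return [
            v is not None and not (isinstance(v, float) and math.isnan(v)) and v >= threshold
            for v in values
        ]
    return [
        v is not None and not (isinstance(v, float) and math.isnan(v)) and v <= threshold
        for v in values
    ]


@dataclass
class ScanWindow:
    """Per-window scan statistics and outlier flags."""

    window: Window
    fst: float | None
    rod: float | None
    tajima_d_introduced: float | None
    fst_top: bool = False
    rod_top: bool = False
    tajd_bottom: bool = False
    candidate: bool = False


def scan(
    g: GenotypeMatrix,
    pops: PopulationMap,
    introduced: str,
    source: str,
    windows: list[Window],
    fraction: float = 0.05,
    estimator: str = "weir_cockerham",
    require_tajima: bool = True,
) -> list[ScanWindow]:
    """Windowed introduced-vs-source selection scan.

    Computes per-window FST between the two populations, ROD from their
    windowed theta_pi, and the introduced population's Tajima's D, then flags
    the empirical tails at ``fraction``. A window is a candidate when
    (FST top-tail OR ROD top-tail) AND (Tajima's D bottom-tail AND < 0);
    ``require_tajima=False`` drops the Tajima's D conjunct.
    """
    if introduced == source:
        raise ValueError("introduced and source populations must differ")

    fst_res = fst_pair(g, pops, introduced, source, windows=windows, estimator=estimator)
    wd = window_diversity(g, pops, windows, populations=[introduced, source])
    pi_intro = {
        (r.window.chrom, r.window.start): r.theta_pi for r in wd if r.population == introduced
    }
    pi_source = {
        (r.window.chrom, r.window.start): r.theta_pi for r in wd if r.population == source
    }
    tajd = {
        (r.window.chrom, r.window.start): r.tajima_d for r in wd if r.population == introduced
    }

    records: list[ScanWindow] = []
    for w, fst in zip(windows, fst_res.window_fst):
        key = (w.chrom, w.start)
        pi_i, pi_s = pi_intro.get(key), pi_source.get(key)
        r = rod(pi_i, pi_s) if pi_i is not None and pi_s is not None else None
        records.append(ScanWindow(window=w, fst=fst, rod=r, tajima_d_introduced=tajd.get(key)))

    fst_flags = flag_outliers([r.fst for r in records], "top", fraction)
    rod_flags = flag_outliers([r.rod for r in records], "top", fraction)
    tajd_flags = flag_outliers([r.tajima_d_introduced for r in records], "bottom", fraction)
    for r, f, o, t in zip(records, fst_flags, rod_flags, tajd_flags):
        r.fst_top, r.rod_top, r.tajd_bottom = f, o, t
        if require_tajima:
            negative = r.tajima_d_introduced is not None and r.tajima_d_introduced < 0
            r.candidate = (f or o) and t and negative
        else:
            r.candidate = f or o
    return records


@dataclass
class CandidateRegion:
    """Maximal merged extent of candidate windows, with overlapping genes."""

    chrom: str
    start: int
    end: int
    n_windows: int
    gene_ids: list[str] = field(default_factory=list)


def merge_candidate_windows(records: list[ScanWindow]) -> list[CandidateRegion]:
    """Merge overlapping or book-ended candidate windows per chromosome."""
    by_chrom: dict[str, list[Window]] = {}
    for r in records:
        if r.candidate:
            by_chrom.setdefault(r.window.chrom, []).append(r.window)
    regions: list[CandidateRegion] = []
    for chrom in sorted(by_chrom):
        wins = sorted(by_chrom[chrom], key=lambda w: w.start)
        cur_start, cur_end, n = wins[0].start, wins[0].end, 1
        for w in wins[1:]:
            if w.start <= cur_end:  # overlap or book-ended
                cur_end = max(cur_end, w.end)
                n += 1
            else:
                regions.append(CandidateRegion(chrom, cur_start, cur_end, n))
                cur_start, cur_end, n = w.start, w.end, 1
        regions.append(CandidateRegion(chrom, cur_start, cur_end, n))
    return regions


def annotate_regions(regions: list[CandidateRegion], gff_path: str) -> list[CandidateRegion]:
    """Attach gene IDs overlapping each region (>= 1 bp) from a GFF3 file.

    GFF coordinates are 1-based inclusive and converted to 0-based half-open
    before intersection. Genes on chromosomes absent from the regions are
    ignored.
    """
    db = gffutils.create_db(
        gff_path, ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    genes = [(f.seqid, f.start - 1, f.end, f.id) for f in db.features_of_type("gene")]
    region_chroms = {r.chrom for r in regions}
    for seqid in {g[0] for g in genes} - region_chroms:
        logger.info("annotate_regions: GFF chromosome %s has no candidate region", seqid)
    for region in regions:
        region.gene_ids = sorted(
            {
                gid
                for seqid, gs, ge, gid in genes
                if seqid == region.chrom and gs < region.end and ge > region.start
            }
        )
    return regions


def merge_and_annotate(
    records: list[ScanWindow], gff_path: str | None = None
) -> list[CandidateRegion]:
    """Merge candidate windows into regions and (optionally) annotate genes."""
    regions = merge_candidate_windows(records)
    if gff_path is not None:
        regions = annotate_regions(regions, gff_path)
    return regions


def scan_frame(records: list[ScanWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.window.chrom for r in records],
            "start": [r.window.start for r in records],
            "end": [r.window.end for r in records],
            "fst": [r.fst for r in records],
            "rod": [r.rod for r in records],
            "tajima_d": [r.tajima_d_introduced for r in records],
            "fst_top": [r.fst_top for r in records],
            "rod_top": [r.rod_top for r in records],
            "tajd_bottom": [r.tajd_bottom for r in records],
            "candidate": [r.candidate for r in records],
        }
    )


def regions_bed(regions: list[CandidateRegion], path: str) -> None:
    """Write candidate regions as BED (0-based half-open, as stored)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.n_windows}\n")


def gene_list_frame(regions: list[CandidateRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        for gid in r.gene_ids:
            rows.append((r.chrom, r.start, r.end, gid))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def total_unique_genes(regions: list[CandidateRegion]) -> int:
    """Distinct genes over all regions (a gene counts once globally)."""
    return len({gid for r in regions for gid in r.gene_ids})
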