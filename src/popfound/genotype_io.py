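"""Genotype matrix I/O: VCF reading/writing, population maps, SNP filtering.

The central container is :class:`GenotypeMatrix`, a diploid ALT-dosage matrix
(samples x sites) with per-site chromosome labels and 1-based positions, as in
VCF. All downstream statistics operate on dosages; phase is discarded on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger("popfound")

#: Sentinel dosage for a missing genotype (no-call or half-call).
MISSING: int = -1

_VALID_DOSAGES = frozenset({0, 1, 2, MISSING})


@dataclass
class GenotypeMatrix:
    """Diploid ALT-allele dosage matrix for biallelic SNPs.

    Parameters
    ----------
    dosages
        Integer array of shape (n_samples, n_sites) with values in
        {0, 1, 2, MISSING}.
    chrom
        Per-site chromosome label, length n_sites.
    positions
        Per-site 1-based bp coordinate (VCF convention), strictly increasing
        within each chromosome.
    sample_ids
        Ordered sample names, length n_samples.
    site_ids
        Ordered site identifiers (VCF ID column or "chrom:pos").
    """

    dosages: np.ndarray
    chrom: np.ndarray
    positions: np.ndarray
    sample_ids: list[str]
    site_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x sites)")
        n_samples, n_sites = self.dosages.shape
        if n_samples < 2:
            raise ValueError("a GenotypeMatrix needs at least 2 samples")
        if len(self.sample_ids) != n_samples:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.chrom) != n_sites or len(self.positions) != n_sites:
            raise ValueError("chrom/positions length does not match dosage columns")
        if not self.site_ids:
            self.site_ids = [f"{c}:{p}" for c, p in zip(self.chrom, self.positions)]
        bad = set(np.unique(self.dosages)) - _VALID_DOSAGES
        if bad:
            raise ValueError(f"invalid dosage values: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (samples x sites) mask, True where the genotype is missing."""
        return self.dosages == MISSING

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given site indices (in order)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            chrom=self.chrom[index],
            positions=self.positions[index],
            sample_ids=list(self.sample_ids),
            site_ids=[self.site_ids[i] for i in np.atleast_1d(index)],
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[index, :],
            chrom=self.chrom.copy(),
            positions=self.positions.copy(),
            sample_ids=[self.sample_ids[i] for i in index],
            site_ids=list(self.site_ids),
        )

    def allele_counts(self, sample_index: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (ALT allele count, non-missing allele count).

        Restricted to ``sample_index`` rows when given.
        """
        d = self.dosages if sample_index is None else self.dosages[sample_index, :]
        called = d != MISSING
        alt = np.where(called, d, 0).sum(axis=0)
        return alt.astype(np.int64), 2 * called.sum(axis=0).astype(np.int64)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and list(self.chrom) == list(other.chrom)
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.dosages, other.dosages)
        )


@dataclass
class PopulationMap:
    """Assignment of each sample to exactly one population label."""

    assignments: dict[str, str]

    @property
    def populations(self) -> list[str]:
        """Population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.assignments.values():
            seen.setdefault(p)
        return list(seen)

    def samples_of(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    def indices_of(self, population: str, sample_ids: list[str]) -> np.ndarray:
        """Row indices of a population's samples within ``sample_ids``.

        Raises ``KeyError`` if the population is absent from the map.
        """
        if population not in self.assignments.values():
            raise KeyError(f"population {population!r} not in population map")
        members = {s for s, p in self.assignments.items() if p == population}
        return np.array([i for i, s in enumerate(sample_ids) if s in members], dtype=np.int64)

    def validate_against(self, g: GenotypeMatrix) -> None:
        missing = [s for s in g.sample_ids if s not in self.assignments]
        if missing:
            raise ValueError(f"samples without a population label: {missing[:5]}")


@dataclass
class FilterReport:
    """Accounting of the SNP-filter pass (missing-rate then MAF criteria)."""

    n_input: int
    n_removed_missing: int
    n_removed_maf: int
    n_kept: int
    max_missing_rate: float
    min_maf: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"sites in: {self.n_input}; removed for missing rate >= "
            f"{self.max_missing_rate}: {self.n_removed_missing}; removed for "
            f"MAF <= {self.min_maf}: {self.n_removed_maf}; kept: {self.n_kept}"
        )


def read_population_map(path: str) -> PopulationMap:
    """Read a two-column (sample_id, population) whitespace/TSV text file.

    Lines starting with '#' are comments.
    """
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'sample population'")
            assignments[parts[0]] = parts[1]
    return PopulationMap(assignments)


def write_population_map(pops: PopulationMap, path: str) -> None:
    with open(path, "w") as fh:
        for s, p in pops.assignments.items():
            fh.write(f"{s}\t{p}\n")


def read_vcf(path: str, region: str | None = None) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are loaded; multiallelic and non-SNP records
    are skipped with a logged count. Genotypes become ALT-dosages; no-calls
    and half-calls become :data:`MISSING`. Phase is ignored.

    Parameters
    ----------
    path
        Path to a VCF 4.x file (plain or bgzipped).
    region
        Optional "chrom" or "chrom:start-end" restriction (1-based inclusive
        bounds); records outside it are dropped during the scan.
    """
    vcf = VCF(path, gts012=False)
    sample_ids = list(vcf.samples)
    if len(sample_ids) < 2:
        raise ValueError("VCF must contain at least 2 samples")

    chroms: list[str] = []
    positions: list[int] = []
    site_ids: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped = 0

    want = _parse_region(region)
    for rec in vcf:
        if want is not None:
            c, lo, hi = want
            if rec.CHROM != c or not (lo <= rec.POS <= hi):
                continue
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_skipped += 1
            continue
        # genotype array: (n_samples, 3) = allele1, allele2, phased flag
        gt = np.asarray(rec.genotype.array())
        if gt.shape[0] != len(sample_ids):
            raise ValueError(
                f"record {rec.CHROM}:{rec.POS}: sample count mismatch vs header"
            )
        a1, a2 = gt[:, 0], gt[:, 1]
        dos = a1 + a2
        dos[(a1 < 0) | (a2 < 0)] = MISSING  # no-call or half-call
        chroms.append(rec.CHROM)
        positions.append(rec.POS)
        site_ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        rows.append(dos.astype(np.int8))
    vcf.close()

    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    if not rows:
        raise ValueError(f"no biallelic SNP records found in {path}")
    return GenotypeMatrix(
        dosages=np.stack(rows, axis=1),
        chrom=np.array(chroms, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        sample_ids=sample_ids,
        site_ids=site_ids,
    )


def _parse_region(region: str | None) -> tuple[str, int, float] | None:
    if region is None:
        return None
    if ":" not in region:
        return region, 1, float("inf")
    chrom, span = region.split(":", 1)
    lo, hi = span.replace(",", "").split("-")
    return chrom, int(lo), int(hi)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write a minimal GT-only VCF 4.2 representation of the matrix.

    REF/ALT are placeholder A/T alleles; ``read_vcf(write_vcf(g)) == g``.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, ln in _chrom_extents(g).items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        for j in range(g.n_sites):
            gts = "\t".join(_GT_STRINGS[int(d)] for d in g.dosages[:, j])
            fh.write(
                f"{g.chrom[j]}\t{g.positions[j]}\t{g.site_ids[j]}\tA\tT\t.\t.\t.\tGT\t{gts}\n"
            )


def _chrom_extents(g: GenotypeMatrix) -> dict[str, int]:
    out: dict[str, int] = {}
    for c, p in zip(g.chrom, g.positions):
        out[c] = max(out.get(c, 0), int(p) + 1)
    return out


def minor_allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """Per-site minor-allele frequency over non-missing alleles (NaN if no calls)."""
    alt, total = g.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
    return np.fmin(p, 1.0 - p)


def filter_sites(
    g: GenotypeMatrix,
    max_missing_rate: float = 0.5,
    min_maf: float = 0.01,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the SNP quality filters used for downstream analysis.

    A site is kept iff its per-site missing fraction is strictly below
    ``max_missing_rate`` AND its minor-allele frequency (computed on
    non-missing alleles) is strictly above ``min_maf``. Both inequalities are
    strict, so boundary sites are removed.
    """
    if not 0.0 <= max_missing_rate <= 1.0:
        raise ValueError("max_missing_rate must be in [0, 1]")
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")

    miss_rate = g.missing_mask.mean(axis=0)
    pass_missing = miss_rate < max_missing_rate
    maf = minor_allele_frequencies(g)
    pass_maf = np.nan_to_num(maf, nan=0.0) > min_maf

    keep = pass_missing & pass_maf
    report = FilterReport(
        n_input=g.n_sites,
        n_removed_missing=int((~pass_missing).sum()),
        n_removed_maf=int((pass_missing & ~pass_maf).sum()),
        n_kept=int(keep.sum()),
        max_missing_rate=max_missing_rate,
        min_maf=min_maf,
    )
    if report.n_kept == 0:
        logger.warning("filter_sites removed every site")
    return g.take_sites(np.flatnonzero(keep)), report
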