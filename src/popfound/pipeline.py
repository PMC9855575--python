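"""End-to-end orchestration: filter -> diversity -> FST -> PCA -> NJ ->
migration -> LD -> selection scan, with report files mirroring the study's
table layouts.

Every stage writes plain TSV/newick/BED files into the output directory and
the resolved configuration is serialised alongside them, so a report
directory is reproducible from config + inputs alone (fixed seeds make the
simulation mode byte-identical across runs).
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diversity as dv
from . import differentiation as df
from . import genotype_io as gio
from . import ld as ldm
from . import migration as mig
from . import selection_scan as scan_mod
from . import structure as st
from . import synthetic_data as syn

logger = logging.getLogger("popfound")


def setup_logging(log_path: str | None = None, level: int = logging.INFO) -> None:
    """Route package logs to stderr and optionally a file (no timestamps,
    so report directories stay byte-identical under a fixed seed)."""
    logger.setLevel(level)
    logger.handlers.clear()
    fmt = logging.Formatter("%(levelname)s %(name)s: %(message)s")
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(fmt)
    logger.addHandler(h)
    if log_path:
        fh = logging.FileHandler(log_path, mode="w")
        fh.setFormatter(fmt)
        logger.addHandler(fh)


@dataclass
class RunConfig:
    """Pipeline settings; defaults are the study's printed parameters.

    Either ``vcf`` + ``popmap`` point at real inputs, or ``simulate=True``
    generates the default founder scenario. All thresholds default to the
    published analysis settings: 10 kb windows with 5 kb steps, missing rate
    < 0.5, MAF > 0.01, 1000 migration bootstraps with a 0.2 edge filter and
    a 5% empirical outlier tail.
    """

    outdir: str = "popfound_out"
    vcf: str | None = None
    popmap: str | None = None
    gff: str | None = None
    simulate: bool = False
    window_size: int = 10_000
    step: int = 5_000
    max_missing: float = 0.5
    min_maf: float = 0.01
    fst_estimator: str = "weir_cockerham"
    ld_max_dist: int = 50_000
    ld_bin_width: int = 5_000
    ld_max_pairs: int = 1_000_000
    migration_statistic: str = "gst"
    migration_bootstraps: int = 1000
    migration_filter_threshold: float = 0.2
    scan_fraction: float = 0.05
    introduced: str | None = None
    source: str | None = None
    per_variant: bool = False
    seed: int = 0
    scenario: dict = field(default_factory=dict)  # overrides for ScenarioConfig

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        """Load a flat key-value YAML config; unknown keys are errors."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _load_inputs(cfg: RunConfig, outdir: Path) -> tuple[gio.GenotypeMatrix, gio.PopulationMap]:
    if cfg.simulate:
        overrides = dict(cfg.scenario)
        overrides.setdefault("seed", cfg.seed)
        sc = syn.ScenarioConfig(**overrides)
        g, pops, truth = syn.simulate_unlinked(sc)
        gio.write_vcf(g, str(outdir / "simulated.vcf"))
        gio.write_population_map(pops, str(outdir / "simulated.popmap.txt"))
        truth.to_dataframe().to_csv(outdir / "simulated.truth.tsv", sep="\t", index=False)
        if cfg.introduced is None:
            cfg.introduced = sc.introduced_label
        if cfg.source is None:
            cfg.source = sc.source_pop
        return g, pops
    if not cfg.vcf or not cfg.popmap:
        raise ValueError("provide vcf and popmap, or set simulate: true")
    g = gio.read_vcf(cfg.vcf)
    pops = gio.read_population_map(cfg.popmap)
    pops.validate_against(g)
    return g, pops


def run_all(cfg: RunConfig) -> Path:
    """Run every stage and return the report directory.

    Any stage failure raises with the stage named; outputs written before the
    failure are left in place.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    setup_logging(str(outdir / "run.log"))
    cfg.to_file(str(outdir / "config.used.yaml"))

    stage = "load"
    try:
        g, pops = _load_inputs(cfg, outdir)

        stage = "filter"
        g, report = gio.filter_sites(g, cfg.max_missing, cfg.min_maf)
        logger.info("filter: %s", report)
        (outdir / "filter_report.txt").write_text(str(report) + "\n")

        stage = "windows"
        windows = dv.make_windows(
            dv.chrom_lengths_from_matrix(g), cfg.window_size, cfg.step
        )

        stage = "diversity"
        summary = dv.diversity_summary(g, pops, windows, per_variant=cfg.per_variant)
        dv.summary_frame(summary).to_csv(
            outdir / "diversity_summary.tsv", sep="\t", index=False, float_format="%.6g"
        )
        wd = dv.window_diversity(g, pops, windows, per_variant=cfg.per_variant)
        dv.window_diversity_frame(wd).to_csv(
            outdir / "window_diversity.tsv", sep="\t", index=False, float_format="%.6g"
        )

        stage = "fst"
        fst = df.fst_matrix(g, pops, windows=windows, estimator=cfg.fst_estimator)
        df.fst_matrix_frame(fst, pops.populations).to_csv(
            outdir / "fst_matrix.tsv", sep="\t", float_format="%.6g"
        )
        df.window_fst_frame(fst, windows).to_csv(
            outdir / "window_fst.tsv", sep="\t", index=False, float_format="%.6g"
        )

        stage = "pca"
        pc = st.pca(g)
        _write_pca(pc, outdir)

        stage = "nj"
        dm = st.p_distance(g)
        dm.to_phylip(str(outdir / "p_distance.phylip"))
        _, newick = st.nj_tree(dm)
        (outdir / "nj_tree.nwk").write_text(newick + "\n")

        stage = "migration"
        net = mig.directional_network(
            g,
            pops,
            statistic=cfg.migration_statistic,
            bootstraps=cfg.migration_bootstraps,
            filter_threshold=cfg.migration_filter_threshold,
            seed=cfg.seed,
        )
        net.edge_frame().to_csv(
            outdir / "migration_edges.tsv", sep="\t", index=False, float_format="%.6g"
        )

        stage = "ld"
        frames = []
        for population in pops.populations:
            curve = ldm.ld_decay(
                g,
                pops,
                population,
                max_dist=cfg.ld_max_dist,
                bin_width=cfg.ld_bin_width,
                max_pairs=cfg.ld_max_pairs,
                seed=cfg.seed,
            )
            frames.append(curve.to_frame())
        pd.concat(frames).to_csv(
            outdir / "ld_decay.tsv", sep="\t", index=False, float_format="%.6g"
        )

        stage = "scan"
        if cfg.introduced and cfg.source:
            records = scan_mod.scan(
                g,
                pops,
                cfg.introduced,
                cfg.source,
                windows,
                fraction=cfg.scan_fraction,
                estimator=cfg.fst_estimator,
            )
            scan_mod.scan_frame(records).to_csv(
                outdir / "scan_windows.tsv", sep="\t", index=False, float_format="%.6g"
            )
            regions = scan_mod.merge_and_annotate(records, cfg.gff)
            scan_mod.regions_bed(regions, str(outdir / "candidate_regions.bed"))
            scan_mod.gene_list_frame(regions).to_csv(
                outdir / "candidate_genes.tsv", sep="\t", index=False
            )
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return outdir


def _write_pca(pc: st.PCAResult, outdir: Path) -> None:
    k = pc.coordinates.shape[1]
    frame = pd.DataFrame(
        pc.coordinates, columns=[f"PC{i + 1}" for i in range(k)], index=pc.sample_ids
    )
    frame.index.name = "sample"
    frame.to_csv(outdir / "pca_scores.tsv", sep="\t", float_format="%.6g")
    pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(k)],
            "variance_explained": pc.variance_explained,
        }
    ).to_csv(outdir / "pca_variance.tsv", sep="\t", index=False, float_format="%.6g")
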