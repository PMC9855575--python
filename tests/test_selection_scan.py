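import numpy as np
import pytest

from popfound import (
    ScanWindow,
    ScenarioConfig,
    filter_sites,
    flag_outliers,
    inject_sweep,
    merge_and_annotate,
    rod,
    scan,
    simulate_unlinked,
)
from popfound.diversity import Window, chrom_lengths_from_matrix, make_windows
from popfound.selection_scan import merge_candidate_windows, total_unique_genes

GFF_TOY = """##gff-version 3
chr1\tsrc\tgene\t12001\t14000\t.\t+\t.\tID=gene_in
chr1\tsrc\tgene\t60001\t61000\t.\t-\t.\tID=gene_out
chrZ\tsrc\tgene\t1\t500\t.\t+\t.\tID=gene_other_chrom
"""


class TestRod:
    @pytest.mark.parametrize(
        "intro,source,expected",
        [(0.004, 0.004, 0.0), (0.0, 0.004, 1.0), (0.0034, 0.0045, 0.2444)],
    )
    def test_values(self, intro, source, expected):
        assert rod(intro, source) == pytest.approx(expected, abs=5e-5)

    def test_zero_source_is_null(self):
        assert rod(0.001, 0.0) is None

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            rod(-0.1, 0.2)


class TestFlagOutliers:
    def test_top_five_of_hundred_distinct(self):
        values = list(range(100))
        flags = flag_outliers(values, "top", 0.05)
        assert sum(flags) == 5
        assert all(flags[i] for i in range(95, 100))

    def test_all_equal_all_flagged(self):
        flags = flag_outliers([1.0] * 10, "top", 0.05)
        assert all(flags)

    def test_bottom_matches_sort_oracle(self, rng):
        values = list(rng.normal(size=60))
        flags = flag_outliers(values, "bottom", 0.1)
        k = int(np.ceil(0.1 * 60))
        cutoff = sorted(values)[k - 1]
        assert flags == [v <= cutoff for v in values]

    def test_nulls_never_flagged(self):
        values = [None, 5.0, float("nan"), 1.0, 2.0, 3.0, 4.0]
        flags = flag_outliers(values, "top", 0.2)
        assert flags[0] is False and flags[2] is False
        assert flags[1]  # 5.0 is the single largest non-null


def _scan_fixture(seed, sweep=True):
    g, pops, _ = simulate_unlinked(ScenarioConfig(seed=seed))
    g, _ = filter_sites(g)
    if sweep:
        g = inject_sweep(g, pops, "Mischief", "chr1", 100_000, 120_000)
    windows = make_windows(chrom_lengths_from_matrix(g), 10_000, 5_000)
    return g, pops, windows


class TestScan:
    def test_positive_control_block_is_detected(self):
        """A hard-swept 20 kb block in the introduced population is flagged."""
        g, pops, windows = _scan_fixture(seed=101)
        records = scan(g, pops, "Mischief", "Lingshui", windows)
        in_block = [
            r for r in records
            if r.window.chrom == "chr1" and 100_000 <= r.window.start and r.window.end <= 120_000
        ]
        assert any(r.candidate for r in in_block)
        # the swept windows carry high ROD and negative Tajima's D
        assert max(r.rod for r in in_block) > 0.5
        assert min(r.tajima_d_introduced for r in in_block) < 0

    def test_neutral_data_has_almost_no_candidates(self):
        g, pops, windows = _scan_fixture(seed=102, sweep=False)
        records = scan(g, pops, "Mischief", "Lingshui", windows)
        assert sum(r.candidate for r in records) / len(records) < 0.02

    def test_candidates_subset_of_tajima_bottom_tail(self):
        g, pops, windows = _scan_fixture(seed=103)
        records = scan(g, pops, "Mischief", "Lingshui", windows)
        for r in records:
            if r.candidate:
                assert r.tajd_bottom and (r.fst_top or r.rod_top)
                assert r.tajima_d_introduced < 0

    def test_dropping_tajima_conjunct_only_grows_candidate_set(self):
        g, pops, windows = _scan_fixture(seed=103)
        strict = scan(g, pops, "Mischief", "Lingshui", windows, require_tajima=True)
        loose = scan(g, pops, "Mischief", "Lingshui", windows, require_tajima=False)
        strict_set = {r.window for r in strict if r.candidate}
        loose_set = {r.window for r in loose if r.candidate}
        assert strict_set <= loose_set

    def test_same_population_rejected(self):
        g, pops, windows = _scan_fixture(seed=104, sweep=False)
        with pytest.raises(ValueError):
            scan(g, pops, "Mischief", "Mischief", windows)


def _fake_records(starts, chrom="chr1", size=10_000):
    return [
        ScanWindow(
            window=Window(chrom, s, s + size), fst=None, rod=None,
            tajima_d_introduced=None, candidate=True,
        )
        for s in starts
    ]


class TestMergeAndAnnotate:
    def test_interval_merge_enumeration(self):
        records = _fake_records([0, 5_000, 20_000])
        regions = merge_candidate_windows(records)
        assert [(r.start, r.end) for r in regions] == [(0, 15_000), (20_000, 30_000)]
        assert [r.n_windows for r in regions] == [2, 1]

    def test_book_ended_windows_merge(self):
        regions = merge_candidate_windows(_fake_records([0, 10_000]))
        assert [(r.start, r.end) for r in regions] == [(0, 20_000)]

    def test_no_candidates_no_regions(self):
        records = _fake_records([])
        assert merge_and_annotate(records) == []

    def test_gene_overlap_against_gff(self, tmp_path):
        gff = tmp_path / "toy.gff3"
        gff.write_text(GFF_TOY)
        records = _fake_records([10_000])  # region [10k, 20k)
        regions = merge_and_annotate(records, str(gff))
        assert regions[0].gene_ids == ["gene_in"]  # 12,001-14,000 intersects
        assert total_unique_genes(regions) == 1

    def test_region_invariants(self):
        g, pops, windows = _scan_fixture(seed=105)
        records = scan(g, pops, "Mischief", "Lingshui", windows)
        regions = merge_candidate_windows(records)
        n_candidates = sum(r.candidate for r in records)
        assert len(regions) <= n_candidates
        total_len = sum(r.end - r.start for r in regions)
        assert total_len <= sum(r.window.size for r in records if r.candidate)
        # merged regions are disjoint per chromosome
        by_chrom = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2
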